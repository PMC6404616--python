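import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenolscreen as ps
from phenolscreen.errors import (
    ConfigError,
    NoValidConcentrationError,
    PlateNormalizationError,
    UndefinedGSVError,
)
from phenolscreen.fitness import (
    NO_CALL,
    NORMAL,
    RESISTANT,
    SENSITIVE,
    ScreenConfig,
    aggregate_replicates,
    classify_sensitivity,
    compute_gsv,
    consensus_call,
    score_screen,
    select_screening_concentration,
    sensitive_sets,
)


class TestComputeGSV:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((80, 80, 100, 100), 1.0),
            ((0, 90, 100, 100), 0.0),
            ((40, 80, 90, 90), 0.5),
        ],
    )
    def test_worked_examples(self, args, expected):
        assert compute_gsv(*args) == pytest.approx(expected)

    def test_zero_untreated_is_undefined(self):
        with pytest.raises(UndefinedGSVError):
            compute_gsv(10, 0, 100, 100)

    def test_zero_wt_rejects_plate(self):
        with pytest.raises(PlateNormalizationError):
            compute_gsv(10, 10, 0, 100)
        with pytest.raises(PlateNormalizationError):
            compute_gsv(10, 10, 100, 0)

    @settings(max_examples=50, derandomize=True)
    @given(
        scale_t=st.floats(0.01, 100),
        scale_u=st.floats(0.01, 100),
        d=st.floats(0.1, 1000),
        wt=st.floats(0.1, 1000),
    )
    def test_invariant_under_plate_rescaling(self, scale_t, scale_u, d, wt):
        """GSV is unchanged by global rescaling of either plate's densities."""
        base = compute_gsv(d, d * 2, wt, wt * 3)
        scaled = compute_gsv(
            d * scale_t, d * 2 * scale_u, wt * scale_t, wt * 3 * scale_u
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_wildtype_self_normalizes_to_one(self):
        assert compute_gsv(37.0, 91.0, 37.0, 91.0) == pytest.approx(1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "gsv,expected",
        [
            (0.11, SENSITIVE),   # lowest observed score in a DNA-repair panel
            (0.5, SENSITIVE),    # inclusive boundary
            (2.0, RESISTANT),    # inclusive boundary
            (24.03, RESISTANT),  # highest observed score
            (1.0, NORMAL),
            (0.51, NORMAL),
            (1.99, NORMAL),
            (0.0, SENSITIVE),
        ],
    )
    def test_threshold_boundaries(self, gsv, expected):
        assert classify_sensitivity(gsv) == expected

    def test_negative_gsv_rejected(self):
        with pytest.raises(ValueError):
            classify_sensitivity(-0.1)

    @settings(max_examples=100, derandomize=True)
    @given(a=st.floats(0, 30), b=st.floats(0, 30))
    def test_monotone_ordering(self, a, b):
        """gsv1 <= gsv2 never produces (RESISTANT, SENSITIVE)."""
        lo, hi = sorted((a, b))
        order = {SENSITIVE: 0, NORMAL: 1, RESISTANT: 2}
        assert order[classify_sensitivity(lo)] <= order[classify_sensitivity(hi)]


class TestAggregateAndConsensus:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.4, 0.6], 0.5), ([0.5], 0.5), ([0.2, 0.3, 0.4], 0.3)],
    )
    def test_mean_aggregation(self, values, expected):
        score = aggregate_replicates("s", "BHA", values)
        assert score.gsv == pytest.approx(expected)
        assert score.n_replicates == len(values)

    def test_undefined_trials_skipped(self):
        score = aggregate_replicates("s", "BHA", [0.4, None, 0.6])
        assert score.gsv == pytest.approx(0.5)
        assert score.n_replicates == 2

    def test_all_undefined_gives_no_call_record(self):
        score = aggregate_replicates("s", "BHA", [None, None])
        assert score.gsv is None

    @pytest.mark.parametrize(
        "calls,m_of_t,expected",
        [
            ([SENSITIVE] * 3 + [NORMAL], (3, 4), SENSITIVE),
            ([SENSITIVE, SENSITIVE, NORMAL, NORMAL], (3, 4), NO_CALL),
            ([SENSITIVE], (1, 1), SENSITIVE),
            ([SENSITIVE, NO_CALL, SENSITIVE], (2, 3), SENSITIVE),
            ([NO_CALL, NO_CALL, SENSITIVE], (2, 3), NO_CALL),
            ([SENSITIVE, RESISTANT], (1, 2), NO_CALL),  # tie -> NO_CALL
        ],
    )
    def test_consensus(self, calls, m_of_t, expected):
        assert consensus_call(calls, m_of_t) == expected

    def test_invalid_m_of_t(self):
        with pytest.raises(ConfigError):
            consensus_call([SENSITIVE], (2, 1))


class TestScreenScoring:
    def test_noiseless_screen_reproduces_planted_sets_exactly(self):
        truth, tables = ps.synthdata.simulate_screen(
            n_strains=100, frac_sensitive=0.2, frac_resistant=0.1,
            noise_cv=0.0, n_replicates=2, seed=13,
        )
        scores = score_screen(tables)
        called_sens = {
            (r.strain, r.compound)
            for r in scores.itertuples()
            if r.call == SENSITIVE
        }
        called_res = {
            (r.strain, r.compound)
            for r in scores.itertuples()
            if r.call == RESISTANT
        }
        assert called_sens == truth.sensitive_truth
        assert called_res == truth.resistant_truth

    def test_noisy_screen_recovers_most_planted(self, small_screen):
        truth, tables = small_screen
        scores = score_screen(tables)
        sens = sensitive_sets(scores)
        called = {(s, c) for c, genes in sens.items() for s in genes}
        tp = len(called & truth.sensitive_truth)
        assert tp / len(truth.sensitive_truth) >= 0.9
        assert tp / len(called) >= 0.9

    def test_missing_wt_rejects_table(self):
        df = pd.DataFrame({"rep1": [1.0]}, index=["s1"])
        with pytest.raises(PlateNormalizationError):
            score_screen({"BHA": {"treated": df, "control": df}})


class TestScreeningConcentration:
    def test_worked_example(self):
        fracs = {0.1: (0.50, 0.95), 0.3: (0.10, 0.55), 0.9: (0.01, 0.05)}
        conc, (f_wt, f_grow) = select_screening_concentration(fracs)
        assert conc == 0.3
        assert (f_wt, f_grow) == (0.10, 0.55)

    def test_everything_killed_raises(self):
        fracs = {0.5: (0.0, 0.02), 1.0: (0.0, 0.0)}
        with pytest.raises(NoValidConcentrationError):
            select_screening_concentration(fracs)

    def test_matches_brute_force_scan(self):
        """Chosen dose equals the exhaustive-scan optimum on a simulated
        library with a planted effect spectrum."""
        rng = np.random.default_rng(21)
        n = 400
        # per-strain tolerance: dose at which growth halves
        tol = rng.lognormal(mean=np.log(0.4), sigma=0.8, size=n)
        concs = [0.05, 0.1, 0.2, 0.4, 0.8, 1.6]
        growth = pd.DataFrame(
            {c: 1.0 / (1.0 + (c / tol) ** 2) for c in concs},
            index=[f"s{i}" for i in range(n)],
        )
        fracs = ps.fitness.screening_fractions(growth)
        picked, _ = select_screening_concentration(fracs)

        # independent brute-force scan of the stated criterion
        best, best_gap = None, np.inf
        for c in concs:
            f_wt = float((growth[c] >= 0.75).mean())
            f_grow = float((growth[c] >= 0.10).mean())
            if f_grow > 0.10 and abs(f_wt - 0.10) < best_gap:
                best, best_gap = c, abs(f_wt - 0.10)
        assert picked == best
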