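"""Growth score values (GSV), sensitivity classification, replicate
aggregation, consensus calls, and screening-concentration selection.

The GSV of a deletion strain under a compound is the ratio of its treated
over untreated colony density, normalized by the same ratio for the
wild-type strain on the same plate pair:

    GSV = (d_treated / d_untreated) / (wt_treated / wt_untreated)

GSV = 1 means wild-type-like growth; GSV <= 0.5 calls a strain sensitive
and GSV >= 2.0 resistant (both boundaries inclusive). Replicate trials are
averaged arithmetically before classification; an m-of-t consensus rule is
available for screens that call each trial separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    NoValidConcentrationError,
    PlateNormalizationError,
    UndefinedGSVError,
)
from .screenio import WT_STRAIN

SENSITIVE = "SENSITIVE"
NORMAL = "NORMAL"
RESISTANT = "RESISTANT"
NO_CALL = "NO_CALL"

CALL_CATEGORIES = (SENSITIVE, NORMAL, RESISTANT)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and consensus rule for a screen.

    ``t_sens``/``t_res`` are the inclusive GSV boundaries for sensitive and
    resistant calls. ``m_of_t`` is the consensus rule (m required concordant
    calls out of t trials): (2, 2) for a duplicate genomic screen, (3, 4)
    for a focused four-trial rescreen.
    """

    t_sens: float = 0.5
    t_res: float = 2.0
    m_of_t: tuple[int, int] = (2, 2)
    wt_strain: str = WT_STRAIN
    profile_log_floor: float = 0.05

    def __post_init__(self):
        if not (0 < self.t_sens < 1 < self.t_res):
            raise ConfigError("need 0 < t_sens < 1 < t_res")
        m, t = self.m_of_t
        if not (1 <= m <= t):
            raise ConfigError("need 1 <= m <= t in m_of_t")


#: Consensus preset for the focused rescreen mode ("at least three of four
#: trials impaired").
RESCREEN_CONFIG = ScreenConfig(m_of_t=(3, 4))

DEFAULT_CONFIG = ScreenConfig()


@dataclass
class GrowthScore:
    """Per-strain, per-condition growth score with replicate provenance.

    ``gsv`` is the arithmetic mean of the defined replicate values, or None
    when no trial yielded a defined score (the strain then gets NO_CALL —
    an undefined GSV is never stored silently as a number).
    """

    strain: str
    compound: str
    gsv: float | None
    replicate_gsvs: list[float | None] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return sum(v is not None for v in self.replicate_gsvs)

    def __post_init__(self):
        defined = [v for v in self.replicate_gsvs if v is not None]
        if defined and self.gsv is not None:
            assert math.isclose(self.gsv, sum(defined) / len(defined), rel_tol=1e-9)


@dataclass
class SensitivityCall:
    """Categorical call with the thresholds and evidence that produced it."""

    strain: str
    compound: str
    call: str
    t_sens: float
    t_res: float
    n_trials_called: int = 0
    n_trials: int = 0


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def compute_gsv(
    d_treated: float,
    d_untreated: float,
    wt_treated: float,
    wt_untreated: float,
) -> float:
    """GSV = (d_treated/d_untreated) / (wt_treated/wt_untreated).

    A zero (or flagged, i.e. NaN) untreated density leaves the strain's GSV
    undefined → :class:`UndefinedGSVError`. Unusable wild-type densities
    invalidate the whole plate pair → :class:`PlateNormalizationError`.
    """
    if wt_untreated is None or not wt_untreated > 0:
        raise PlateNormalizationError("wild-type untreated density must be > 0")
    if wt_treated is None or not wt_treated > 0:
        raise PlateNormalizationError("wild-type treated density must be > 0")
    if d_untreated is None or not d_untreated > 0:
        raise UndefinedGSVError("untreated density is zero or flagged")
    if d_treated < 0:
        raise ValueError("treated density must be >= 0")
    return (d_treated / d_untreated) / (wt_treated / wt_untreated)


def classify_sensitivity(gsv: float, config: ScreenConfig = DEFAULT_CONFIG) -> str:
    """SENSITIVE if gsv <= t_sens, RESISTANT if gsv >= t_res, else NORMAL.

    Both boundaries are inclusive.
    """
    if gsv < 0:
        raise ValueError("gsv must be >= 0")
    if gsv <= config.t_sens:
        return SENSITIVE
    if gsv >= config.t_res:
        return RESISTANT
    return NORMAL


def aggregate_replicates(
    strain: str,
    compound: str,
    trial_gsvs: Sequence[float | None],
) -> GrowthScore:
    """Average the defined per-trial GSVs into one score.

    All trials undefined → a GrowthScore with ``gsv=None`` (NO_CALL record).
    """
    defined = [v for v in trial_gsvs if v is not None]
    gsv = sum(defined) / len(defined) if defined else None
    return GrowthScore(
        strain=strain,
        compound=compound,
        gsv=gsv,
        replicate_gsvs=list(trial_gsvs),
    )


def consensus_call(trial_calls: Sequence[str], m_of_t: tuple[int, int]) -> str:
    """m-of-t consensus over per-trial calls.

    The final call is the category appearing in at least m trials; if no
    category (or more than one) reaches m, or fewer than m trials are
    evaluable, the result is NO_CALL.
    """
    m, t = m_of_t
    if not (1 <= m <= t):
        raise ConfigError("need 1 <= m <= t")
    evaluable = [c for c in trial_calls if c in CALL_CATEGORIES]
    if len(evaluable) < m:
        return NO_CALL
    counts = {cat: evaluable.count(cat) for cat in CALL_CATEGORIES}
    winners = [cat for cat, n in counts.items() if n >= m]
    return winners[0] if len(winners) == 1 else NO_CALL


# ---------------------------------------------------------------------------
# screen-level scoring
# ---------------------------------------------------------------------------

def score_screen(
    tables: Mapping[str, Mapping[str, pd.DataFrame]],
    config: ScreenConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Score a whole screen from treated/control density tables.

    ``tables[compound]["treated"|"control"]`` are strain × replicate
    density DataFrames including the wild-type strain. Per replicate, each
    strain's GSV is computed against the wild-type ratio of the same
    replicate; replicates are then averaged and the mean classified.

    Returns a tidy DataFrame with columns strain, compound, gsv,
    n_replicates, call (gsv is NaN for NO_CALL records).
    """
    records = []
    for compound, pair in tables.items():
        treated, control = pair["treated"], pair["control"]
        if config.wt_strain not in treated.index:
            raise PlateNormalizationError(
                f"wild-type strain {config.wt_strain!r} absent from {compound} table"
            )
        for strain in treated.index:
            if strain == config.wt_strain:
                continue
            trial_vals: list[float | None] = []
            for rep in treated.columns:
                try:
                    trial_vals.append(
                        compute_gsv(
                            treated.at[strain, rep],
                            control.at[strain, rep],
                            treated.at[config.wt_strain, rep],
                            control.at[config.wt_strain, rep],
                        )
                    )
                except UndefinedGSVError:
                    trial_vals.append(None)
            score = aggregate_replicates(strain, compound, trial_vals)
            call = (
                classify_sensitivity(score.gsv, config)
                if score.gsv is not None
                else NO_CALL
            )
            records.append(
                {
                    "strain": strain,
                    "compound": compound,
                    "gsv": score.gsv if score.gsv is not None else float("nan"),
                    "n_replicates": score.n_replicates,
                    "call": call,
                }
            )
    return pd.DataFrame(records)


def sensitive_sets(scores: pd.DataFrame) -> dict[str, set[str]]:
    """Per-compound sets of strains called SENSITIVE."""
    out: dict[str, set[str]] = {}
    for compound, grp in scores.groupby("compound"):
        out[compound] = set(grp.loc[grp["call"] == SENSITIVE, "strain"])
    return out


# ---------------------------------------------------------------------------
# screening-concentration selection
# ---------------------------------------------------------------------------

def screening_fractions(
    rel_growth: pd.DataFrame,
    wt_like_min: float = 0.75,
    grow_min: float = 0.10,
) -> dict[float, tuple[float, float]]:
    """Per-concentration fractions of wt-like and growing mutants.

    ``rel_growth`` is strain × concentration growth relative to wild type;
    a mutant is wt-like at >= ``wt_like_min`` and growing at >= ``grow_min``.
    """
    out = {}
    for conc in rel_growth.columns:
        col = rel_growth[conc].dropna()
        out[float(conc)] = (
            float((col >= wt_like_min).mean()),
            float((col >= grow_min).mean()),
        )
    return out


def select_screening_concentration(
    fractions: Mapping[float, tuple[float, float]],
    target_wt_fraction: float = 0.10,
    min_growing_fraction: float = 0.10,
) -> tuple[float, tuple[float, float]]:
    """Pick the screening dose: about 10% of mutants wild-type-like, while
    more than 10% still grow.

    Among concentrations with growing fraction strictly above
    ``min_growing_fraction``, returns the one minimizing
    ``|fraction_wt_like − target|`` (ties → lower concentration). Raises
    :class:`NoValidConcentrationError` when no candidate passes the growth
    constraint.
    """
    if len(fractions) < 2:
        raise ConfigError("need at least 2 candidate concentrations")
    valid = {
        c: fr for c, fr in fractions.items() if fr[1] > min_growing_fraction
    }
    if not valid:
        raise NoValidConcentrationError(
            "no concentration leaves more than "
            f"{min_growing_fraction:.0%} of mutants growing"
        )
    best = min(valid, key=lambda c: (abs(valid[c][0] - target_wt_fraction), c))
    return best, valid[best]
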