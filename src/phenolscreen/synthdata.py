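"""Synthetic screens, plate images, annotation universes and dose-response
curves with known ground truth.

Every generator here is a pure function of its parameters and a seed, so the
whole downstream pipeline (densitometry → GSV → calls → overlaps →
clustering → enrichment) can be exercised against planted truth without any
external data. The statistical structure mirrors a genome-wide deletion
library screen against phenolic stress compounds:

* per-strain multiplicative fitness effects rho (1 = wild-type-like,
  <1 inhibited, >1 resistant), with sensitive effects drawn uniformly from
  [0.1, 0.4] and resistant from [2.5, 6] — bracketing the observed dynamic
  range of growth score values in such screens (roughly 0.1 to 24);
* multiplicative lognormal measurement noise (colony densitometry errors
  scale with intensity);
* plate images as grids of smooth-edged disks on a sloped background with
  additive pixel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .screenio import EMPTY, WT_STRAIN, CompoundCondition, GeneAnnotation, PlateLayout

DEFAULT_EFFECT_DISTRIBUTIONS = {
    "sensitive": (0.1, 0.4),
    "resistant": (2.5, 6.0),
}

#: GSV at or below this value marks a strain as truly sensitive in the
#: planted truth (matches the downstream sensitivity threshold).
SENSITIVITY_TRUTH_THRESHOLD = 0.5


@dataclass
class ScreenTruth:
    """Ground truth for one simulated screen."""

    strains: list[str]
    compounds: list[str]
    effect: pd.DataFrame  # strains x compounds, true rho
    sensitive_truth: set[tuple[str, str]]
    resistant_truth: set[tuple[str, str]]
    noise_cv: float
    seed: int


@dataclass
class RenderParams:
    """Geometry and noise parameters for plate-image rendering.

    All lengths in pixels. ``intensity_per_density`` converts a density in
    arbitrary units into peak spot intensity. The invariants
    ``grid_pitch_px > 2 * spot_radius_px`` and
    ``saturation > background maximum`` are enforced at construction.
    """

    spot_radius_px: int = 6
    grid_pitch_px: int = 20
    margin_px: int = 20
    background_level: float = 200.0
    gradient_amplitude: float = 30.0
    pixel_noise_sd: float = 1.0
    saturation: float = 65535.0
    intensity_per_density: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_pitch_px <= 2 * self.spot_radius_px:
            raise ConfigError("grid_pitch_px must exceed 2 * spot_radius_px")
        if self.saturation <= self.background_level + self.gradient_amplitude:
            raise ConfigError("saturation must exceed the background maximum")


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = -0.5 * sigma * sigma
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


def simulate_screen(
    n_strains: int = 1000,
    compounds: tuple[str, ...] = ("BHA", "BHT", "BPA"),
    frac_sensitive: float = 0.1,
    frac_resistant: float = 0.0,
    effect_distributions: dict | None = None,
    noise_cv: float = 0.15,
    n_replicates: int = 3,
    base_density: float = 1000.0,
    seed: int = 0,
) -> tuple[ScreenTruth, dict[str, dict[str, pd.DataFrame]]]:
    """Simulate a deletion-library fitness screen.

    For each compound, a fraction ``frac_sensitive`` of strains gets a true
    relative fitness rho drawn from ``effect_distributions["sensitive"]``
    (default uniform on [0.1, 0.4]), ``frac_resistant`` from the resistant
    interval, and the rest rho = 1. Measured densities are

        treated  = base_density * rho * lognormal(1, noise_cv)
        control  = base_density * lognormal(1, noise_cv)

    with an independent noise draw per strain, replicate and plate. The
    wild-type strain (``"wt"``) is appended with rho = 1 everywhere.

    Returns ``(truth, tables)`` where ``tables[compound]`` holds two
    DataFrames (``"treated"``, ``"control"``) indexed by strain with one
    column per replicate.
    """
    if not (0 <= frac_sensitive <= 1) or not (0 <= frac_resistant <= 1):
        raise ConfigError("fractions must lie in [0, 1]")
    if frac_sensitive + frac_resistant > 1:
        raise ConfigError("frac_sensitive + frac_resistant must be <= 1")
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    if n_strains < 1:
        raise ConfigError("n_strains must be >= 1")
    dists = dict(DEFAULT_EFFECT_DISTRIBUTIONS)
    if effect_distributions:
        dists.update(effect_distributions)
    for key in ("sensitive", "resistant"):
        lo, hi = dists[key]
        if not (0 < lo <= hi):
            raise ConfigError(f"effect_distributions[{key!r}] must satisfy 0 < lo <= hi")

    rng = np.random.default_rng(seed)
    strains = [f"strain{i:04d}" for i in range(n_strains)]
    compounds = list(compounds)

    effect = pd.DataFrame(1.0, index=strains + [WT_STRAIN], columns=compounds)
    n_sens = int(round(frac_sensitive * n_strains))
    n_res = int(round(frac_resistant * n_strains))
    for comp in compounds:
        picked = rng.choice(n_strains, size=n_sens + n_res, replace=False)
        lo, hi = dists["sensitive"]
        effect.loc[[strains[i] for i in picked[:n_sens]], comp] = rng.uniform(
            lo, hi, size=n_sens
        )
        lo, hi = dists["resistant"]
        effect.loc[[strains[i] for i in picked[n_sens:]], comp] = rng.uniform(
            lo, hi, size=n_res
        )

    all_strains = strains + [WT_STRAIN]
    cols = [f"rep{r + 1}" for r in range(n_replicates)]
    tables: dict[str, dict[str, pd.DataFrame]] = {}
    for comp in compounds:
        rho = effect[comp].to_numpy()[:, None]
        treated = base_density * rho * _lognormal_factor(
            rng, noise_cv, (len(all_strains), n_replicates)
        )
        control = base_density * _lognormal_factor(
            rng, noise_cv, (len(all_strains), n_replicates)
        )
        tables[comp] = {
            "treated": pd.DataFrame(treated, index=all_strains, columns=cols),
            "control": pd.DataFrame(control, index=all_strains, columns=cols),
        }

    sens = {
        (s, c)
        for s in strains
        for c in compounds
        if effect.at[s, c] <= SENSITIVITY_TRUTH_THRESHOLD
    }
    res = {(s, c) for s in strains for c in compounds if effect.at[s, c] >= 2.0}
    truth = ScreenTruth(
        strains=strains,
        compounds=compounds,
        effect=effect,
        sensitive_truth=sens,
        resistant_truth=res,
        noise_cv=noise_cv,
        seed=seed,
    )
    return truth, tables


# ---------------------------------------------------------------------------
# plate-image rendering
# ---------------------------------------------------------------------------

def spot_centers(layout: PlateLayout, params: RenderParams) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of row and column spot centers for a layout."""
    rows = params.margin_px + params.grid_pitch_px * np.arange(layout.n_rows)
    cols = params.margin_px + params.grid_pitch_px * np.arange(layout.n_cols)
    return rows.astype(float), cols.astype(float)


def render_plate_image(
    density_grid: np.ndarray,
    layout: PlateLayout,
    params: RenderParams | None = None,
) -> np.ndarray:
    """Render a density grid as a grayscale plate image.

    Each spot is a hard disk of radius ``spot_radius_px`` with Gaussian edge
    smoothing (sigma = radius / 4), whose background-subtracted integrated
    intensity is proportional to the requested density. The background is a
    smooth linear gradient plus Gaussian pixel noise; the result is clipped
    at the saturation ceiling. Deterministic for a fixed ``params.seed``.
    """
    params = params or RenderParams()
    density_grid = np.asarray(density_grid, dtype=float)
    if density_grid.shape != layout.shape:
        raise ValueError(
            f"density grid shape {density_grid.shape} != layout {layout.shape}"
        )
    if np.any(density_grid < 0):
        raise ValueError("densities must be non-negative")

    rng = np.random.default_rng(params.seed)
    h = 2 * params.margin_px + params.grid_pitch_px * (layout.n_rows - 1) + 1
    w = 2 * params.margin_px + params.grid_pitch_px * (layout.n_cols - 1) + 1
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    img = params.background_level + params.gradient_amplitude * (
        0.5 * yy / max(h - 1, 1) + 0.5 * xx / max(w - 1, 1)
    )

    r = float(params.spot_radius_px)
    sigma = r / 4.0
    row_c, col_c = spot_centers(layout, params)
    # local window big enough to hold the smoothed edge (r + 4 sigma = 2r)
    half = int(math.ceil(2 * r)) + 1
    from scipy.special import erf

    for i in range(layout.n_rows):
        for j in range(layout.n_cols):
            d = density_grid[i, j]
            if d == 0:
                continue
            cy, cx = row_c[i], col_c[j]
            y0, y1 = int(cy) - half, int(cy) + half + 1
            x0, x1 = int(cx) - half, int(cx) + half + 1
            ys = np.arange(max(y0, 0), min(y1, h))
            xs = np.arange(max(x0, 0), min(x1, w))
            dist = np.hypot(ys[:, None] - cy, xs[None, :] - cx)
            profile = 0.5 * (1.0 - erf((dist - r) / (math.sqrt(2) * sigma)))
            img[np.ix_(ys, xs)] += d * params.intensity_per_density * profile

    if params.pixel_noise_sd > 0:
        img += rng.normal(0.0, params.pixel_noise_sd, size=img.shape)
    return np.clip(img, 0.0, params.saturation)


def write_plate_image(img: np.ndarray, path) -> None:
    """Write an intensity array as 16-bit grayscale PNG or TIFF."""
    import imageio.v3 as iio

    arr = np.clip(img, 0, 65535).astype(np.uint16)
    iio.imwrite(str(path), arr)


def layout_for_grid(
    n_rows: int,
    n_cols: int,
    strains: list[str] | None = None,
    wt_positions: set[tuple[int, int]] | None = None,
    plate_id: str = "synthetic",
    condition: CompoundCondition | None = None,
) -> PlateLayout:
    """Convenience builder: fill a grid row-major with strain ids.

    Positions beyond the strain list become EMPTY; ``wt_positions`` default
    to the four corners.
    """
    if wt_positions is None:
        wt_positions = {(0, 0), (0, n_cols - 1), (n_rows - 1, 0), (n_rows - 1, n_cols - 1)}
    pos_map: dict[tuple[int, int], str] = {}
    k = 0
    strains = strains or []
    for i in range(n_rows):
        for j in range(n_cols):
            if (i, j) in wt_positions:
                pos_map[(i, j)] = WT_STRAIN
            elif k < len(strains):
                pos_map[(i, j)] = strains[k]
                k += 1
            else:
                pos_map[(i, j)] = EMPTY
    return PlateLayout(
        plate_id=plate_id,
        n_rows=n_rows,
        n_cols=n_cols,
        position_map=pos_map,
        wt_positions=set(wt_positions),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# annotation universe with planted enrichment
# ---------------------------------------------------------------------------

def simulate_annotation_universe(
    n_genes: int = 2000,
    n_terms: int = 100,
    term_size_range: tuple[int, int] = (20, 200),
    planted: list[tuple[str, float]] | None = None,
    query_size: int = 300,
    seed: int = 0,
) -> tuple[GeneAnnotation, dict]:
    """Generate a gene universe, a query set and GO-like terms.

    Non-planted terms are uniform random subsets of the universe, so their
    overlap with the query is exactly hypergeometric (the null). For each
    planted ``(term_id, fold)``, the query∩term overlap is constructed to be
    ``round(fold * n * K / N)`` — ``fold`` times the hypergeometric
    expectation. Term ids are ``term0000``...; planted ids must use that
    namespace or are assigned in order.

    Returns ``(annotation, truth)`` with ``truth = {"query": set,
    "planted": {term_id: constructed overlap}}``.
    """
    if n_genes < 1 or query_size > n_genes:
        raise ConfigError("need 1 <= query_size <= n_genes")
    lo, hi = term_size_range
    if not (1 <= lo <= hi):
        raise ConfigError("term_size_range must satisfy 1 <= lo <= hi")
    if n_terms > 0 and hi > n_genes:
        raise ConfigError("term size exceeds universe")
    planted = list(planted or [])
    for _, fold in planted:
        if fold < 1:
            raise ConfigError("planted folds must be >= 1")
    if len(planted) > n_terms:
        raise ConfigError("more planted terms than n_terms")

    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    query_idx = rng.choice(n_genes, size=query_size, replace=False)
    query = set(genes[query_idx])
    in_query = np.zeros(n_genes, dtype=bool)
    in_query[query_idx] = True
    query_pool = np.flatnonzero(in_query)
    other_pool = np.flatnonzero(~in_query)

    term_map: dict[str, tuple[str, frozenset[str]]] = {}
    truth_planted: dict[str, int] = {}
    for t in range(n_terms):
        term_id = f"term{t:04d}"
        size = int(rng.integers(lo, hi + 1))
        term_map[term_id] = (
            f"synthetic process {t}",
            frozenset(genes[rng.choice(n_genes, size=size, replace=False)]),
        )
    # overwrite planted terms with constructed overlaps
    for rank, (pid, fold) in enumerate(planted):
        term_id = pid if pid in term_map else f"term{rank:04d}"
        size = int(rng.integers(lo, hi + 1))
        k_target = int(round(fold * query_size * size / n_genes))
        k_target = min(k_target, size, query_size)
        if size - k_target > n_genes - query_size:
            raise ConfigError(
                f"planted term {term_id}: cannot place {size - k_target} "
                "members outside the query"
            )
        members_q = rng.choice(query_pool, size=k_target, replace=False)
        members_o = rng.choice(other_pool, size=size - k_target, replace=False)
        term_map[term_id] = (
            f"planted process fold={fold}",
            frozenset(genes[np.concatenate([members_q, members_o])]),
        )
        truth_planted[term_id] = k_target

    annotation = GeneAnnotation(universe=set(genes), term_map=term_map)
    return annotation, {"query": query, "planted": truth_planted}


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def simulate_dose_response(
    ic50: float,
    hill_slope: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a logistic dose-response growth curve.

    Growth fraction relative to the solvent control:

        g(c) = 1 / (1 + (c / ic50)^hill_slope) + N(0, noise_sd)

    so g(0) = 1 (no inhibition) and g(ic50) = 0.5 (50% inhibition).
    """
    if ic50 <= 0:
        raise ConfigError("ic50 must be > 0")
    if hill_slope <= 0:
        raise ConfigError("hill_slope must be > 0")
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc < 0):
        raise ConfigError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    growth = 1.0 / (1.0 + (conc / ic50) ** hill_slope)
    if noise_sd > 0:
        # measured densities cannot go negative
        growth = np.clip(growth + rng.normal(0.0, noise_sd, size=conc.shape), 0.0, None)
    return pd.DataFrame({"concentration": conc, "growth_fraction": growth})
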