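"""Hypergeometric gene-set over-representation, multiple-testing
correction, and the radial bubble-plot layout.

The enrichment statistic is the upper-tail hypergeometric probability

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

for an overlap of k genes between a query of size n and a term of size K
drawn from a universe of N — the standard over-representation test,
evaluated in log space for numerical stability at genomic sizes. The
observed k is included in the tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .screenio import GeneAnnotation

logger = logging.getLogger(__name__)

#: Significance reference used in reports and figure metadata.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentInput:
    """The 2x2 geometry of one test: universe N, term K, query n, overlap k."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError("need 0 <= K, n <= N")
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError("need 0 <= k <= min(n, K)")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    counts: EnrichmentInput
    p_raw: float
    p_corrected: float | None = None
    correction_method: str | None = None
    significant: bool | None = None


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def _log_binom(a: float, b: float) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_log_pmf(i: int, n: int, K: int, N: int) -> float:
    """log P(X = i) for the hypergeometric overlap distribution."""
    return (
        _log_binom(K, i)
        + _log_binom(N - K, n - i)
        - _log_binom(N, n)
    )


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k): probability of an overlap at least as large as observed.

    Computed as a log-space sum of exact log-pmf terms. ``k <= 0`` covers
    the whole support (returns 1); ``k > min(n, K)`` is an empty sum
    (returns 0).
    """
    EnrichmentInput(N=N, K=K, n=n, k=max(min(k, min(n, K)), 0))
    upper = min(n, K)
    if k <= max(0, n + K - N):
        return 1.0
    if k > upper:
        return 0.0
    i = np.arange(k, upper + 1, dtype=float)
    logs = (
        _log_binom(K, i)
        + _log_binom(N - K, n - i)
        - _log_binom(N, n)
    )
    return float(min(1.0, math.exp(logsumexp(logs))))


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

def correct_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing correction: Bonferroni or Benjamini–Hochberg.

    Bonferroni returns min(1, m·p); BH is the standard step-up with
    monotonicity enforcement. All inputs must lie in (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ConfigError(f"unknown correction method {method!r}")


# ---------------------------------------------------------------------------
# enrichment over an annotation
# ---------------------------------------------------------------------------

def enrich_gene_sets(
    query: set[str],
    annotation: GeneAnnotation,
    alpha: float = DEFAULT_ALPHA,
    method: str = "bonferroni",
    include_flags: bool = True,
) -> list[EnrichmentResult]:
    """Test every term (and optionally every binary flag) for
    over-representation in the query.

    Query genes outside the universe are dropped with a logged warning.
    Terms and flags are corrected together at ``alpha``; results come back
    sorted by raw p ascending, ties broken by term id.
    """
    if not annotation.universe:
        raise ConfigError("empty gene universe")
    N = len(annotation.universe)
    outside = set(query) - annotation.universe
    if outside:
        logger.warning(
            "%d query genes outside the universe were dropped (e.g. %s)",
            len(outside),
            sorted(outside)[:3],
        )
    q = set(query) & annotation.universe
    n = len(q)

    gene_sets: dict[str, tuple[str, frozenset[str]]] = dict(annotation.term_map)
    if include_flags:
        for label, members in annotation.flag_sets().items():
            gene_sets[f"flag:{label}"] = (label, frozenset(members))

    results = []
    for term_id, (name, members) in gene_sets.items():
        K = len(members)
        k = len(q & members)
        p = hypergeom_upper_tail(k, n, K, N)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=name,
                counts=EnrichmentInput(N=N, K=K, n=n, k=k),
                p_raw=p,
            )
        )
    if results:
        corrected = correct_pvalues([r.p_raw for r in results], method=method)
        for r, pc in zip(results, corrected):
            r.p_corrected = float(pc)
            r.correction_method = method
            r.significant = pc < alpha
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def results_records(results: list[EnrichmentResult]) -> list[dict]:
    """TSV-ready records (term, k, n, K, N, p_raw, p_corrected, significant)."""
    return [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.counts.k,
            "n": r.counts.n,
            "K": r.counts.K,
            "N": r.counts.N,
            "p_raw": r.p_raw,
            "p_corrected": r.p_corrected if r.p_corrected is not None else "",
            "significant": int(bool(r.significant)),
        }
        for r in results
    ]


# ---------------------------------------------------------------------------
# bubble layout
# ---------------------------------------------------------------------------

#: p-value color bins (upper edges) covering (0, alpha].
COLOR_BIN_EDGES = (1e-10, 1e-5, 1e-3, 1e-2, 0.05)


@dataclass
class BubbleEntry:
    term_id: str
    gene_count: int
    radius: float
    radial_distance: float
    angle_rad: float
    color_bin: int  # index into COLOR_BIN_EDGES (smaller = more significant)


@dataclass
class BubbleLayout:
    entries: list[BubbleEntry]
    radius_scale: float
    distance_scale: float
    center_label: str = ""


def bubble_layout(
    results: list[EnrichmentResult],
    radius_scale: float = 1.0,
    distance_scale: float = 4.0,
    center_label: str = "",
    max_iter: int = 500,
) -> BubbleLayout:
    """Radial bubble plot: each significant term is a circle whose radius
    and distance from the center are both proportional to its gene count
    (separate scale constants), colored by corrected p-value bin.

    Angles start rank-ordered (largest term first) and are then jittered
    deterministically until no two circle boundaries overlap (or
    ``max_iter`` passes elapse).
    """
    for r in results:
        if not r.significant:
            raise ValueError(f"term {r.term_id} is not significant; filter first")
    if not results:
        return BubbleLayout([], radius_scale, distance_scale, center_label)

    ordered = sorted(results, key=lambda r: (-r.counts.k, r.term_id))
    m = len(ordered)
    angles = np.array([2 * math.pi * i / m for i in range(m)])
    counts = np.array([r.counts.k for r in ordered], dtype=float)
    radii = radius_scale * counts
    dists = distance_scale * counts

    def centers(a):
        return np.stack([dists * np.cos(a), dists * np.sin(a)], axis=1)

    step = 2 * math.pi / (8 * m)
    for _ in range(max_iter):
        c = centers(angles)
        moved = False
        for i in range(m):
            for j in range(i + 1, m):
                gap = np.hypot(*(c[i] - c[j])) - (radii[i] + radii[j])
                if gap < 1e-9:
                    # push the pair apart azimuthally, deterministic direction
                    angles[i] -= step
                    angles[j] += step
                    moved = True
        if not moved:
            break

    entries = []
    for r, ang in zip(ordered, angles):
        pc = r.p_corrected if r.p_corrected is not None else r.p_raw
        color_bin = next(
            (b for b, edge in enumerate(COLOR_BIN_EDGES) if pc <= edge),
            len(COLOR_BIN_EDGES) - 1,
        )
        entries.append(
            BubbleEntry(
                term_id=r.term_id,
                gene_count=r.counts.k,
                radius=radius_scale * r.counts.k,
                radial_distance=distance_scale * r.counts.k,
                angle_rad=float(ang % (2 * math.pi)),
                color_bin=color_bin,
            )
        )
    return BubbleLayout(entries, radius_scale, distance_scale, center_label)


def plot_bubbles(layout: BubbleLayout, path=None):
    """Render a BubbleLayout with matplotlib; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap("viridis", len(COLOR_BIN_EDGES))
    fig, ax = plt.subplots(figsize=(6, 6))
    for e in layout.entries:
        x = e.radial_distance * math.cos(e.angle_rad)
        y = e.radial_distance * math.sin(e.angle_rad)
        ax.add_patch(
            plt.Circle((x, y), e.radius, color=cmap(e.color_bin), alpha=0.7)
        )
        ax.annotate(e.term_id, (x, y), ha="center", fontsize=6)
    lim = max(
        (e.radial_distance + e.radius for e in layout.entries), default=1.0
    ) * 1.1
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.annotate(layout.center_label, (0, 0), ha="center", fontweight="bold")
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
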