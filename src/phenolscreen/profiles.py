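"""Cross-compound overlap accounting and hierarchical clustering of GSV
profiles.

Overlap accounting reports, for the per-compound sensitive gene sets, the
pairwise intersections (inclusive of the higher-order intersection), the
union, and per-compound unique counts/fractions, with the inclusion–
exclusion identity checked on every summary. When only printed marginal
counts are available (no gene lists), :func:`overlap_from_counts` solves
for whatever the marginals determine and reports the rest as unavailable.

Profiles are log2-converted GSVs clipped at a floor, so the sensitive and
resistant thresholds sit symmetrically at −1 and +1; clustering is
agglomerative (default Euclidean distance, average linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import EmptyMatrixError


@dataclass
class OverlapSummary:
    """Set-overlap bookkeeping for up to n compounds.

    ``pairwise`` counts are inclusive of the higher-order intersection
    (|A∩B| counts genes also in C). ``unique`` is per-compound exclusive
    membership. Fields that the available inputs do not determine are None.
    """

    names: list[str]
    sizes: dict[str, int]
    pairwise: dict[frozenset, int | None]
    triple: int | None
    union: int | None
    unique: dict[str, int | None]
    unique_fraction: dict[str, float | None]
    sets: dict[str, set] | None = None

    def check_inclusion_exclusion(self) -> None:
        """Assert |A∪B∪C| = Σ|X| − Σ|X∩Y| + |A∩B∩C| when fully determined."""
        if self.union is None or any(v is None for v in self.pairwise.values()):
            return
        total = sum(self.sizes.values()) - sum(self.pairwise.values())
        if len(self.names) >= 3:
            if self.triple is None:
                return
            total += self.triple
        assert total == self.union, (
            f"inclusion-exclusion violated: {total} != {self.union}"
        )


def overlap_analysis(sets: Mapping[str, set]) -> OverlapSummary:
    """Exact overlap summary from full per-compound gene sets."""
    names = list(sets)
    sets = {k: set(v) for k, v in sets.items()}
    sizes = {k: len(v) for k, v in sets.items()}
    union_set = set().union(*sets.values()) if sets else set()
    pairwise = {
        frozenset((a, b)): len(sets[a] & sets[b]) for a, b in combinations(names, 2)
    }
    triple = None
    if len(names) == 3:
        a, b, c = names
        triple = len(sets[a] & sets[b] & sets[c])
    unique = {}
    for k in names:
        others = set().union(*(sets[o] for o in names if o != k)) if len(names) > 1 else set()
        unique[k] = len(sets[k] - others)
    union = len(union_set)
    frac = {k: (unique[k] / union if union else None) for k in names}
    summary = OverlapSummary(
        names=names,
        sizes=sizes,
        pairwise=pairwise,
        triple=triple,
        union=union,
        unique=unique,
        unique_fraction=frac,
        sets=sets,
    )
    summary.check_inclusion_exclusion()
    return summary


def overlap_from_counts(
    sizes: Mapping[str, int],
    pairwise: Mapping[tuple[str, str], int] | None = None,
    triple: int | None = None,
    unique: Mapping[str, int] | None = None,
) -> OverlapSummary:
    """Overlap summary from printed marginal counts (no gene lists).

    ``pairwise`` intersections are inclusive of the triple. For two
    compounds a missing |A∩B| can be recovered from one given unique count
    (|A∩B| = |A| − A-only). Quantities the inputs leave undetermined are
    reported as None rather than guessed.
    """
    names = list(sizes)
    sizes = dict(sizes)
    pw: dict[frozenset, int | None] = {
        frozenset(p): None for p in combinations(names, 2)
    }
    for (a, b), v in (pairwise or {}).items():
        pw[frozenset((a, b))] = v
    given_unique = dict(unique or {})

    if len(names) == 2:
        a, b = names
        key = frozenset((a, b))
        if pw[key] is None:
            for k, other in ((a, b), (b, a)):
                if k in given_unique:
                    pw[key] = sizes[k] - given_unique[k]
                    break
        inter = pw[key]
        if inter is None:
            uniq = {k: given_unique.get(k) for k in names}
            union = None
        else:
            uniq = {a: sizes[a] - inter, b: sizes[b] - inter}
            union = sizes[a] + sizes[b] - inter
    elif len(names) == 3:
        uniq = {}
        for k in names:
            others = [o for o in names if o != k]
            inters = [pw[frozenset((k, o))] for o in others]
            if all(v is not None for v in inters) and triple is not None:
                uniq[k] = sizes[k] - inters[0] - inters[1] + triple
            else:
                uniq[k] = given_unique.get(k)
        if all(v is not None for v in pw.values()) and triple is not None:
            union = sum(sizes.values()) - sum(pw.values()) + triple
        else:
            union = None
    else:
        raise ValueError("overlap_from_counts supports 2 or 3 compounds")

    frac = {
        k: (uniq[k] / union if uniq.get(k) is not None and union else None)
        for k in names
    }
    summary = OverlapSummary(
        names=names,
        sizes=sizes,
        pairwise=pw,
        triple=triple,
        union=union,
        unique=uniq,
        unique_fraction=frac,
    )
    summary.check_inclusion_exclusion()
    return summary


def overlap_records(summary: OverlapSummary) -> list[dict]:
    """Flatten a summary into TSV-ready records."""
    rows = []
    for k in summary.names:
        rows.append(
            {
                "quantity": f"size:{k}",
                "count": summary.sizes[k],
                "fraction_of_union": "",
            }
        )
    for pair, v in summary.pairwise.items():
        a, b = sorted(pair)
        rows.append(
            {"quantity": f"intersection:{a}&{b}", "count": v if v is not None else "NA",
             "fraction_of_union": ""}
        )
    if len(summary.names) == 3:
        rows.append({"quantity": "intersection:all", "count": summary.triple
                     if summary.triple is not None else "NA", "fraction_of_union": ""})
    rows.append({"quantity": "union", "count": summary.union
                 if summary.union is not None else "NA", "fraction_of_union": ""})
    for k in summary.names:
        u, f = summary.unique[k], summary.unique_fraction[k]
        rows.append(
            {
                "quantity": f"unique:{k}",
                "count": u if u is not None else "NA",
                "fraction_of_union": f"{f:.4f}" if f is not None else "NA",
            }
        )
    return rows


# ---------------------------------------------------------------------------
# profile matrix and clustering
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    """Strains × conditions matrix of converted GSVs: log2(max(gsv, floor))."""

    values: pd.DataFrame
    floor: float
    dropped: list[str] = field(default_factory=list)

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)


def build_profile_matrix(
    scores: pd.DataFrame,
    floor: float = 0.05,
) -> ProfileMatrix:
    """Pivot tidy GSV scores into a log2 profile matrix.

    ``scores`` needs columns strain, compound, gsv (NaN = NO_CALL). Entries
    are log2(max(gsv, floor)); rows containing any NO_CALL are dropped and
    recorded in ``dropped``. Raises :class:`EmptyMatrixError` when nothing
    usable remains.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if scores.empty:
        raise EmptyMatrixError("no scores supplied")
    wide = scores.pivot(index="strain", columns="compound", values="gsv")
    keep = wide.dropna()
    dropped = sorted(set(wide.index) - set(keep.index))
    if keep.empty:
        raise EmptyMatrixError("every strain has at least one NO_CALL")
    converted = np.log2(keep.clip(lower=floor))
    return ProfileMatrix(values=converted, floor=floor, dropped=dropped)


@dataclass
class ClusterResult:
    """Agglomerative clustering of profile rows."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge table
    labels: list[str]
    leaf_order: list[int]
    method: str
    metric: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hierarchical_cluster(
    matrix: ProfileMatrix | pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Cluster profile rows agglomeratively.

    Deterministic given the input row order; SciPy breaks distance ties by
    the lowest cluster index, so permuting rows yields the same tree up to
    leaf relabeling.
    """
    values = matrix.values if isinstance(matrix, ProfileMatrix) else matrix
    if len(values) < 2:
        raise ValueError("need at least 2 rows to cluster")
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("profile matrix contains non-finite entries")
    Z = hierarchy.linkage(pdist(arr, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage_matrix=Z,
        labels=list(values.index),
        leaf_order=list(map(int, order)),
        method=method,
        metric=metric,
    )


def to_newick(result: ClusterResult) -> str:
    """Serialize the merge tree as Newick with branch lengths."""
    tree = hierarchy.to_tree(result.linkage_matrix)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def plot_heatmap(
    matrix: ProfileMatrix,
    result: ClusterResult | None = None,
    path=None,
    vmax: float | None = None,
):
    """Clustered heatmap of log2 GSVs, red = sensitive, blue = resistant.

    Returns the matplotlib figure; writes to ``path`` (PNG/SVG) if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.values
    if result is not None:
        values = values.iloc[result.leaf_order]
    if vmax is None:
        vmax = float(np.abs(values.to_numpy()).max()) or 1.0
    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * values.shape[1], 1 + 0.22 * values.shape[0])
    )
    im = ax.imshow(values.to_numpy(), cmap="RdBu", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(values.shape[1]), values.columns, rotation=45, ha="right")
    ax.set_yticks(range(values.shape[0]), values.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 GSV")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
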