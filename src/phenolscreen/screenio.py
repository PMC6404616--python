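"""Readers and writers for plate layouts, gene annotations, gene sets and
result tables.

File conventions
----------------
* Plate layouts are TSV with fixed columns
  ``plate_id, row, col, strain_id, is_wt, dilution_step`` (unknown extra
  columns are preserved on read but ignored). Grid positions are labelled
  A1-style externally (letters = rows, numbers = columns, both starting at
  A/1) and held 0-based ``(row, col)`` internally.
* Gene sets use the GMT convention: one term per line,
  ``term_id <TAB> description <TAB> member1 <TAB> member2 ...``.
* Binary gene flags (human ortholog, disease associated, kinase, essential)
  are a TSV with one row per gene and one 0/1 column per label.
* Result tables are TSV with a stable column order and fixed float
  precision so that files are diffable across runs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import (
    ConfigError,
    DuplicatePositionError,
    DuplicateTermError,
    LayoutError,
    ParseError,
)

#: Sentinel strain id for an intentionally empty grid position.
EMPTY = "EMPTY"

#: Default wild-type strain identifier.
WT_STRAIN = "wt"

#: Recognized binary flag labels for gene annotations.
FLAG_VOCABULARY = ("human_ortholog", "disease_associated", "kinase", "essential")

LAYOUT_COLUMNS = ("plate_id", "row", "col", "strain_id", "is_wt", "dilution_step")

FLOAT_FMT = "{:.6f}"


# ---------------------------------------------------------------------------
# position labels
# ---------------------------------------------------------------------------

def label_to_index(label: str) -> tuple[int, int]:
    """Convert an A1-style well label to 0-based ``(row, col)``.

    Rows are letters (A=0, ..., Z=25, AA=26, ...), columns are 1-based
    integers. ``"A1" -> (0, 0)``, ``"H12" -> (7, 11)``.
    """
    i = 0
    while i < len(label) and label[i].isalpha():
        i += 1
    if i == 0 or i == len(label):
        raise ParseError(f"malformed position label {label!r}")
    row = 0
    for ch in label[:i].upper():
        row = row * 26 + (string.ascii_uppercase.index(ch) + 1)
    col = int(label[i:])
    if col < 1:
        raise ParseError(f"malformed position label {label!r}")
    return row - 1, col - 1


def index_to_label(row: int, col: int) -> str:
    """Inverse of :func:`label_to_index`: ``(0, 0) -> "A1"``."""
    if row < 0 or col < 0:
        raise ValueError("indices must be non-negative")
    letters = ""
    r = row + 1
    while r > 0:
        r, rem = divmod(r - 1, 26)
        letters = string.ascii_uppercase[rem] + letters
    return f"{letters}{col + 1}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundCondition:
    """One treatment condition: a compound at a concentration in a solvent.

    ``compound == "CONTROL"`` denotes the solvent-only reference and implies
    zero concentration.
    """

    compound: str
    concentration_mM: float = 0.0
    solvent_fraction_pct: float = 1.0
    replicate: int = 1

    def __post_init__(self):
        if self.concentration_mM < 0:
            raise ConfigError("concentration_mM must be >= 0")
        if self.compound == "CONTROL" and self.concentration_mM != 0:
            raise ConfigError("CONTROL condition implies concentration 0")
        if self.replicate < 1:
            raise ConfigError("replicate index must be >= 1")


@dataclass
class PlateLayout:
    """Grid geometry plus the position→strain map for one plate.

    ``position_map`` maps 0-based ``(row, col)`` to a strain id or
    :data:`EMPTY`. ``wt_positions`` marks the wild-type reference spots used
    for per-plate normalization. ``dilution_axis``, when present, is
    ``(axis, factors)`` with ``axis`` one of ``"row"``/``"col"`` and
    ``factors`` the ordered dilution factors along that axis
    (e.g. ``[1e-1, 1e-2, ..., 1e-5]`` for a 1:10–1:100,000 series).
    """

    plate_id: str
    n_rows: int
    n_cols: int
    position_map: dict[tuple[int, int], str]
    wt_positions: set[tuple[int, int]] = field(default_factory=set)
    dilution_axis: tuple[str, list[float]] | None = None
    condition: CompoundCondition | None = None
    wt_strain: str = WT_STRAIN

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise LayoutError("grid dimensions must be positive")
        for (r, c) in self.position_map:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise LayoutError(
                    f"position {index_to_label(r, c)} outside "
                    f"{self.n_rows}x{self.n_cols} grid"
                )
        for pos in self.wt_positions:
            if pos not in self.position_map:
                raise LayoutError(
                    f"wt position {index_to_label(*pos)} not mapped"
                )
            if self.position_map[pos] != self.wt_strain:
                raise LayoutError(
                    f"wt position {index_to_label(*pos)} mapped to "
                    f"{self.position_map[pos]!r}, expected {self.wt_strain!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_rows, self.n_cols

    def strains(self) -> list[str]:
        """Unique non-empty strain ids in row-major order of first occurrence."""
        seen: dict[str, None] = {}
        for pos in sorted(self.position_map):
            s = self.position_map[pos]
            if s != EMPTY and s not in seen:
                seen[s] = None
        return list(seen)


@dataclass
class GeneAnnotation:
    """Gene universe with binary flags and GO-like term membership.

    Invariant: every term member belongs to the universe; flag labels are
    drawn from :data:`FLAG_VOCABULARY`.
    """

    universe: set[str]
    flags: dict[str, set[str]] = field(default_factory=dict)
    term_map: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self):
        for gene, labels in self.flags.items():
            bad = labels - set(FLAG_VOCABULARY)
            if bad:
                raise ConfigError(f"unknown flag labels {sorted(bad)} for {gene}")
        for term, (_, members) in self.term_map.items():
            outside = members - self.universe
            if outside:
                raise ConfigError(
                    f"term {term} has members outside the universe: "
                    f"{sorted(outside)[:5]}"
                )

    def flag_sets(self) -> dict[str, set[str]]:
        """Invert ``flags`` into label → gene-set form for enrichment."""
        out: dict[str, set[str]] = {}
        for gene, labels in self.flags.items():
            for lab in labels:
                out.setdefault(lab, set()).add(gene)
        return out


# ---------------------------------------------------------------------------
# plate layout I/O
# ---------------------------------------------------------------------------

def read_plate_layout(path: str | Path, wt_strain: str = WT_STRAIN) -> PlateLayout:
    """Read a plate layout TSV (columns :data:`LAYOUT_COLUMNS`).

    Rows/cols in the file are A1-style labels or 0-based integers; ``is_wt``
    is 0/1. Raises :class:`DuplicatePositionError` on a repeated position,
    :class:`LayoutError` on invariant violations, and :class:`ParseError`
    (with the line number) on malformed rows.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty layout file")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in LAYOUT_COLUMNS[:5] if c not in header]
    if missing:
        raise ParseError(f"missing layout columns {missing}", line=1)
    idx = {c: header.index(c) for c in header}

    position_map: dict[tuple[int, int], str] = {}
    wt_positions: set[tuple[int, int]] = set()
    dilution_steps: dict[tuple[int, int], int] = {}
    plate_id = None
    max_r = max_c = -1
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < len(LAYOUT_COLUMNS[:5]):
            raise ParseError("too few columns", line=lineno)
        try:
            plate_id = fields[idx["plate_id"]]
            r = _parse_coord(fields[idx["row"]])
            c = _parse_coord(fields[idx["col"]])
            strain = fields[idx["strain_id"]]
            is_wt = fields[idx["is_wt"]] in ("1", "True", "true")
            step = None
            if "dilution_step" in idx and len(fields) > idx["dilution_step"]:
                raw_step = fields[idx["dilution_step"]].strip()
                step = int(raw_step) if raw_step not in ("", "NA") else None
        except (ValueError, IndexError) as exc:
            raise ParseError(str(exc), line=lineno) from exc
        if (r, c) in position_map:
            raise DuplicatePositionError(
                f"position {index_to_label(r, c)} listed twice"
            )
        position_map[(r, c)] = strain
        if is_wt:
            wt_positions.add((r, c))
        if step is not None:
            dilution_steps[(r, c)] = step
        max_r, max_c = max(max_r, r), max(max_c, c)

    if not position_map:
        raise ParseError("layout file has no data rows")
    return PlateLayout(
        plate_id=plate_id or path.stem,
        n_rows=max_r + 1,
        n_cols=max_c + 1,
        position_map=position_map,
        wt_positions=wt_positions,
        dilution_axis=_infer_dilution_axis(dilution_steps),
        wt_strain=wt_strain,
    )


def _parse_coord(text: str) -> int:
    """External coordinates are 1-based (numbers) or letters (rows)."""
    text = text.strip()
    if text.isdigit():
        v = int(text)
        if v < 1:
            raise ValueError(f"coordinates are 1-based, got {text!r}")
        return v - 1
    # single alpha run -> row letter
    if text.isalpha():
        row = 0
        for ch in text.upper():
            row = row * 26 + (string.ascii_uppercase.index(ch) + 1)
        return row - 1
    raise ValueError(f"bad coordinate {text!r}")


def _infer_dilution_axis(
    steps: dict[tuple[int, int], int]
) -> tuple[str, list[float]] | None:
    if not steps:
        return None
    rows = {r for r, _ in steps}
    cols = {c for _, c in steps}
    # dilution varies along exactly one axis
    col_consistent = all(len({steps[p] for p in steps if p[1] == c}) == 1 for c in cols)
    row_consistent = all(len({steps[p] for p in steps if p[0] == r}) == 1 for r in rows)
    if col_consistent and len(cols) > 1:
        ordered = sorted(cols)
        factors = [10.0 ** -steps[next(p for p in steps if p[1] == c)] for c in ordered]
        return ("col", factors)
    if row_consistent and len(rows) > 1:
        ordered = sorted(rows)
        factors = [10.0 ** -steps[next(p for p in steps if p[0] == r)] for r in ordered]
        return ("row", factors)
    return None


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    """Write a layout in canonical form: fixed columns, A1 labels,
    row-major position order."""
    path = Path(path)
    lines = ["\t".join(LAYOUT_COLUMNS)]
    for (r, c) in sorted(layout.position_map):
        step = ""
        if layout.dilution_axis is not None:
            axis, factors = layout.dilution_axis
            k = c if axis == "col" else r
            if k < len(factors):
                import math

                step = str(int(round(-math.log10(factors[k]))))
        lines.append(
            "\t".join(
                [
                    layout.plate_id,
                    index_to_label(r, 0)[:-1],
                    str(c + 1),
                    layout.position_map[(r, c)],
                    "1" if (r, c) in layout.wt_positions else "0",
                    step,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT) and flags
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into ``term_id -> (description, member set)``.

    Members are deduplicated. Raises :class:`ParseError` on a term with no
    members and :class:`DuplicateTermError` on a repeated term id.
    """
    term_map: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError("GMT line needs id, description and >=1 member", line=lineno)
        term_id, desc, members = fields[0], fields[1], fields[2:]
        members = [m for m in members if m]
        if not members:
            raise ParseError(f"term {term_id} has no members", line=lineno)
        if term_id in term_map:
            raise DuplicateTermError(f"term {term_id} defined twice", line=lineno)
        term_map[term_id] = (desc, frozenset(members))
    return term_map


def write_gene_sets(term_map: Mapping[str, tuple[str, frozenset[str]]],
                    path: str | Path) -> None:
    """Write a term map as GMT; members sorted for a canonical byte form."""
    lines = []
    for term_id in sorted(term_map):
        desc, members = term_map[term_id]
        lines.append("\t".join([term_id, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_flags(path: str | Path) -> GeneAnnotation:
    """Read a binary flag table (gene + one 0/1 column per label)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError("empty flags file")
    header = lines[0].split("\t")
    if header[0] != "gene":
        raise ParseError("first column must be 'gene'", line=1)
    labels = header[1:]
    bad = set(labels) - set(FLAG_VOCABULARY)
    if bad:
        raise ParseError(f"unknown flag labels {sorted(bad)}", line=1)
    universe: set[str] = set()
    flags: dict[str, set[str]] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(header):
            raise ParseError("column count mismatch", line=lineno)
        gene = fields[0]
        universe.add(gene)
        on = {lab for lab, v in zip(labels, fields[1:]) if v == "1"}
        if on:
            flags[gene] = on
    return GeneAnnotation(universe=universe, flags=flags)


def write_flags(annotation: GeneAnnotation, path: str | Path,
                labels: Sequence[str] = FLAG_VOCABULARY) -> None:
    lines = ["\t".join(["gene", *labels])]
    for gene in sorted(annotation.universe):
        on = annotation.flags.get(gene, set())
        lines.append("\t".join([gene, *("1" if lab in on else "0" for lab in labels)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results_table(records: Sequence[Mapping], path: str | Path,
                        columns: Sequence[str] | None = None) -> None:
    """Write records as TSV with stable column order and fixed float precision.

    Column order: ``columns`` if given, else the key order of the first
    record. An empty record list yields a header-only file (``columns``
    required in that case).
    """
    records = list(records)
    if columns is None:
        if not records:
            raise ValueError("columns required for an empty record list")
        columns = list(records[0].keys())
    lines = ["\t".join(columns)]
    for rec in records:
        cells = []
        for col in columns:
            v = rec.get(col, "")
            if isinstance(v, float):
                cells.append(FLOAT_FMT.format(v))
            else:
                cells.append(str(v))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results_table(path: str | Path) -> list[dict]:
    """Read back a results TSV; numeric-looking cells become floats/ints."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError("empty results file")
    header = lines[0].split("\t")
    out = []
    for raw in lines[1:]:
        if not raw.strip():
            continue
        rec = {}
        for col, cell in zip(header, raw.split("\t")):
            rec[col] = _coerce(cell)
        out.append(rec)
    return out


def _coerce(cell: str):
    for cast in (int, float):
        try:
            return cast(cell)
        except ValueError:
            continue
    return cell


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration; raise ConfigError on bad YAML."""
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg
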