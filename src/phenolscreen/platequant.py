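"""Digitize plate scan images into per-position colony densities.

The pipeline is: locate the spot grid from 1-D marginal intensity
projections (with an optional small-rotation search), then integrate each
spot over a disk after subtracting a local annulus-median background.
Densities are relative (arbitrary units); only ratios are meaningful
downstream, which is all the growth score requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks
from skimage.transform import rotate as _sk_rotate

from .errors import GridDetectionError, MissingDataError
from .screenio import EMPTY, PlateLayout, index_to_label

FLAG_EMPTY = "EMPTY"
FLAG_SATURATED = "SATURATED"
FLAG_CONTAMINATED = "CONTAMINATED"
FLAG_EDGE = "EDGE"

#: Flags that make a spot unusable for density aggregation. EMPTY is a
#: legitimate biological outcome (no growth) and is not in this set.
DISQUALIFYING_FLAGS = frozenset({FLAG_SATURATED, FLAG_CONTAMINATED, FLAG_EDGE})


@dataclass
class GridFit:
    """Detected spot-grid geometry for one plate image."""

    row_centers: np.ndarray
    col_centers: np.ndarray
    pitch_row: float
    pitch_col: float
    rotation_deg: float
    quality: float  # fraction of expected peaks found, in [0, 1]

    def __post_init__(self):
        if np.any(np.diff(self.row_centers) <= 0) or np.any(np.diff(self.col_centers) <= 0):
            raise GridDetectionError("grid centers must be strictly increasing")


@dataclass
class SpotQuant:
    """Background-corrected integrated density for one grid position."""

    position: tuple[int, int]
    integrated_density: float
    local_background: float
    flags: set[str] = field(default_factory=set)

    @property
    def usable(self) -> bool:
        return not (self.flags & DISQUALIFYING_FLAGS)


# ---------------------------------------------------------------------------
# grid detection
# ---------------------------------------------------------------------------

def _axis_peaks(profile: np.ndarray, expected: int, pitch_guess: float):
    """Find ``expected`` peak positions (subpixel) in a 1-D projection.

    Returns None when the profile does not contain a credible grid.
    """
    # remove the smooth background trend (plate gradient); a low percentile
    # tracks the background even where spot tails cover most of the window
    win = max(int(1.5 * pitch_guess) | 1, 3)
    baseline = percentile_filter(profile, percentile=10, size=win, mode="nearest")
    detrended = profile - baseline
    detrended = np.clip(detrended, 0, None)
    peak_scale = detrended.max()
    if peak_scale <= 0:
        return None
    # noise from the inter-peak valleys (lowest quartile of the detrended
    # profile); peaks dominate the profile so a global MAD would not do
    valley = detrended[detrended <= np.quantile(detrended, 0.25)]
    noise = 1.4826 * np.median(np.abs(valley - np.median(valley))) + 1e-12
    if peak_scale < 8 * noise:
        return None
    for prom_frac in (0.5, 0.25, 0.1):  # relaxation ladder
        peaks, props = find_peaks(
            detrended,
            prominence=max(prom_frac * peak_scale, 4 * noise),
            distance=max(int(0.6 * pitch_guess), 1),
        )
        if len(peaks) >= expected:
            break
    else:
        return None
    if len(peaks) > expected:
        order = np.argsort(props["prominences"])[::-1][:expected]
        peaks = np.sort(peaks[order])
    # subpixel refinement: re-centered intensity centroid in a window just
    # under half a pitch (covers the smoothed spot tails without touching
    # the neighbors)
    centers = []
    half = max(int(0.45 * pitch_guess), 1)
    for p in peaks:
        c = float(p)
        for _ in range(3):
            lo, hi = max(int(round(c)) - half, 0), min(int(round(c)) + half + 1, len(detrended))
            w = detrended[lo:hi]
            if w.sum() <= 0:
                break
            c = float((np.arange(lo, hi) * w).sum() / w.sum())
        centers.append(c)
    centers = np.array(centers)
    # a genuine pinned grid is near-uniformly pitched; irregular spacing
    # means smeared/spurious peaks (e.g. a rotated plate)
    diffs = np.diff(centers)
    if len(diffs) and (np.any(diffs <= 0) or diffs.std() / diffs.mean() > 0.15):
        return None
    return centers


def detect_grid(
    image: np.ndarray,
    expected_rows: int,
    expected_cols: int,
    rotation_tol_deg: float = 2.0,
    rotation_step_deg: float = 0.5,
) -> GridFit:
    """Locate the spot grid via marginal intensity projections.

    Projections along each axis are detrended, peak-called, and refined to
    subpixel centroids. If the unrotated image does not yield the expected
    number of peaks on both axes, an exhaustive small-rotation search
    (±``rotation_tol_deg`` in ``rotation_step_deg`` steps) is attempted;
    rotations beyond the tolerance are never considered, so a plate skewed
    more than that raises :class:`GridDetectionError`.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D single channel")
    if expected_rows < 2 or expected_cols < 2:
        raise ValueError("expected grid must be at least 2x2")

    def attempt(img: np.ndarray):
        row_profile = img.sum(axis=1)
        col_profile = img.sum(axis=0)
        rc = _axis_peaks(row_profile, expected_rows, img.shape[0] / (expected_rows + 1))
        cc = _axis_peaks(col_profile, expected_cols, img.shape[1] / (expected_cols + 1))
        if rc is None or cc is None:
            return None
        return rc, cc

    angles = [0.0]
    n_steps = int(round(rotation_tol_deg / rotation_step_deg))
    for k in range(1, n_steps + 1):
        angles.extend([k * rotation_step_deg, -k * rotation_step_deg])

    best = None
    for ang in angles:
        img = image if ang == 0.0 else _sk_rotate(
            image, ang, preserve_range=True, mode="edge"
        )
        got = attempt(img)
        if got is None:
            continue
        rc, cc = got
        # sharper projections (higher peak contrast) win
        score = img.sum(axis=1).std() + img.sum(axis=0).std()
        if best is None or score > best[0]:
            best = (score, ang, rc, cc)
        if ang == 0.0:
            break  # unrotated success needs no search

    if best is None:
        raise GridDetectionError(
            f"could not locate a {expected_rows}x{expected_cols} grid "
            f"within ±{rotation_tol_deg}° rotation"
        )
    _, ang, rc, cc = best
    return GridFit(
        row_centers=rc,
        col_centers=cc,
        pitch_row=float(np.mean(np.diff(rc))),
        pitch_col=float(np.mean(np.diff(cc))),
        rotation_deg=float(ang),
        quality=1.0,
    )


# ---------------------------------------------------------------------------
# spot quantification
# ---------------------------------------------------------------------------

def _disk_annulus_masks(shape, cy, cx, r, r_out):
    h, w = shape
    y0, y1 = int(math.floor(cy - r_out)), int(math.ceil(cy + r_out)) + 1
    x0, x1 = int(math.floor(cx - r_out)), int(math.ceil(cx + r_out)) + 1
    oob = y0 < 0 or x0 < 0 or y1 > h or x1 > w
    ys = np.arange(max(y0, 0), min(y1, h))
    xs = np.arange(max(x0, 0), min(x1, w))
    dist = np.hypot(ys[:, None] - cy, xs[None, :] - cx)
    return ys, xs, dist, oob


def quantify_spots(
    image: np.ndarray,
    grid: GridFit,
    layout: PlateLayout,
    radius_px: float | None = None,
    empty_threshold: float | None = None,
    saturation_level: float = 65535.0,
) -> list[list[SpotQuant]]:
    """Integrate background-corrected density at every grid position.

    Per position: ``integrated_density = max(0, Σ(pixel − local_background))``
    over a disk of radius ``radius_px`` centered on the grid point, with
    ``local_background`` the median of an annulus spanning radii
    (r, 1.6 r). Flags:

    * ``EDGE`` — the disk/annulus leaves the image (measured anyway on the
      in-bounds pixels, but disqualified downstream);
    * ``SATURATED`` — any disk pixel at or above ``saturation_level``;
    * ``EMPTY`` — density at or below ``empty_threshold`` (default: a
      5-sigma bound on a pure-background integral, estimated from the
      annulus pixel scatter).
    """
    image = np.asarray(image, dtype=float)
    n_rows, n_cols = len(grid.row_centers), len(grid.col_centers)
    if (n_rows, n_cols) != layout.shape:
        raise ValueError(
            f"grid {n_rows}x{n_cols} does not match layout {layout.shape}"
        )
    if radius_px is None:
        radius_px = 0.35 * min(grid.pitch_row, grid.pitch_col)
    r_out = 1.6 * radius_px

    out: list[list[SpotQuant]] = []
    for i in range(n_rows):
        row_q: list[SpotQuant] = []
        for j in range(n_cols):
            cy, cx = grid.row_centers[i], grid.col_centers[j]
            ys, xs, dist, oob = _disk_annulus_masks(image.shape, cy, cx, radius_px, r_out)
            patch = image[np.ix_(ys, xs)]
            disk = dist <= radius_px
            annulus = (dist > radius_px) & (dist <= r_out)
            flags: set[str] = set()
            if oob:
                flags.add(FLAG_EDGE)
            bg = float(np.median(patch[annulus])) if annulus.any() else 0.0
            dens = float(max(0.0, (patch[disk] - bg).sum()))
            if disk.any() and float(patch[disk].max()) >= saturation_level:
                flags.add(FLAG_SATURATED)
            if empty_threshold is None:
                ann = patch[annulus]
                sigma_px = 1.4826 * float(np.median(np.abs(ann - bg))) if ann.size else 0.0
                thr = 5.0 * sigma_px * math.sqrt(max(disk.sum(), 1))
            else:
                thr = empty_threshold
            if dens <= thr:
                flags.add(FLAG_EMPTY)
            row_q.append(
                SpotQuant(
                    position=(i, j),
                    integrated_density=dens,
                    local_background=bg,
                    flags=flags,
                )
            )
        out.append(row_q)
    return out


def quants_to_frame(quants: list[list[SpotQuant]], layout: PlateLayout) -> pd.DataFrame:
    """Flatten a SpotQuant matrix into a tidy per-position table."""
    rows = []
    for row_q in quants:
        for q in row_q:
            i, j = q.position
            rows.append(
                {
                    "position": index_to_label(i, j),
                    "row": i,
                    "col": j,
                    "strain_id": layout.position_map.get((i, j), EMPTY),
                    "integrated_density": q.integrated_density,
                    "local_background": q.local_background,
                    "flags": ";".join(sorted(q.flags)),
                }
            )
    return pd.DataFrame(rows)


def collapse_dilution_series(quants) -> float:
    """Collapse a strain's dilution series into one density: the sum of
    integrated densities over usable spots.

    EMPTY spots are excluded from the sum (no growth contributes zero);
    spots flagged SATURATED, CONTAMINATED or EDGE are disqualified. If every
    spot is disqualified, the strain has no measurement and
    :class:`MissingDataError` is raised. A single-spot assay (pin
    replicator) reduces to the identity.
    """
    quants = list(quants)
    if not quants:
        raise MissingDataError("empty dilution series")
    usable = [q for q in quants if q.usable]
    if not usable:
        raise MissingDataError("all spots in the series are flagged unusable")
    return float(
        sum(q.integrated_density for q in usable if FLAG_EMPTY not in q.flags)
    )
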