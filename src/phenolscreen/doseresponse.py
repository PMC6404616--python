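"""Dose-dependent growth curves and IC50–IC80 estimation.

Growth is read out as culture density relative to the solvent-only control
at matched time; percent inhibition is 100·(1 − treated/control). The
inhibitory concentration IC_x (the dose giving x% inhibition) is estimated
either by monotone interpolation of inhibition against log-concentration,
or by a two-parameter logistic fit

    growth(c) = 1 / (1 + (c / IC50)^h)

inverted at the requested level. The screening-dose window for a fitness
screen is conventionally IC50–IC80.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ExtrapolationError, FitError

__all__ = [
    "DoseResponseCurve",
    "growth_inhibition",
    "estimate_ic",
    "fit_logistic",
]


@dataclass
class DoseResponseCurve:
    """Observed (concentration, growth fraction) points for one compound."""

    points: pd.DataFrame  # columns: concentration, growth_fraction
    compound: str = ""
    ic50: float | None = None
    hill_slope: float | None = None
    residuals: np.ndarray | None = None

    def __post_init__(self):
        pts = self.points.sort_values("concentration").reset_index(drop=True)
        if pts["concentration"].duplicated().any():
            pts = (
                pts.groupby("concentration", as_index=False)["growth_fraction"]
                .mean()
            )
        if (pts["growth_fraction"] < 0).any():
            raise ValueError("growth fractions must be >= 0")
        self.points = pts

    @property
    def concentrations(self) -> np.ndarray:
        return self.points["concentration"].to_numpy(dtype=float)

    @property
    def inhibition_pct(self) -> np.ndarray:
        g = self.points["growth_fraction"].to_numpy(dtype=float)
        return np.clip(100.0 * (1.0 - g), 0.0, None)


def growth_inhibition(od_treated: float, od_control: float) -> float:
    """Percent growth inhibition, 100·(1 − treated/control), floored at 0."""
    if od_control <= 0:
        raise ValueError("control OD must be > 0")
    if od_treated < 0:
        raise ValueError("treated OD must be >= 0")
    return max(0.0, 100.0 * (1.0 - od_treated / od_control))


def _logistic_growth(c, ic50, h):
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, c / ic50, 0.0)
        return 1.0 / (1.0 + ratio**h)


def fit_logistic(curve: DoseResponseCurve) -> tuple[float, float]:
    """Least-squares 2-parameter logistic fit; returns (ic50, hill_slope)."""
    c = curve.concentrations
    g = curve.points["growth_fraction"].to_numpy(dtype=float)
    if len(c) < 4:
        raise FitError("logistic fit needs at least 4 points")
    # initial guess: concentration nearest 50% growth, unit slope
    pos = c[c > 0]
    if pos.size == 0:
        raise FitError("logistic fit needs positive concentrations")
    ic0 = float(pos[np.argmin(np.abs(g[c > 0] - 0.5))]) or float(np.median(pos))
    try:
        popt, _ = curve_fit(
            _logistic_growth,
            c,
            g,
            p0=[ic0, 1.0],
            bounds=([1e-12, 1e-3], [np.inf, 50.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    ic50, h = map(float, popt)
    curve.ic50, curve.hill_slope = ic50, h
    curve.residuals = g - _logistic_growth(c, ic50, h)
    return ic50, h


def estimate_ic(
    curve: DoseResponseCurve,
    level: float,
    method: str = "interp",
) -> float:
    """Concentration producing ``level`` percent growth inhibition.

    ``interp``: monotone linear interpolation of inhibition against
    log10-concentration between the bracketing observed points (linear in
    concentration when the lower bracket is the zero-dose anchor); an exact
    observed hit returns that concentration directly. ``logistic``: invert
    the fitted two-parameter logistic, IC_x = IC50 · (x/(100−x))^(1/h).

    Raises :class:`ExtrapolationError` when the observed inhibition does
    not span the requested level (interp), :class:`FitError` on a
    non-convergent fit (logistic).
    """
    if not (0 < level < 100):
        raise ValueError("level must lie in (0, 100)")

    if method == "logistic":
        ic50, h = (curve.ic50, curve.hill_slope)
        if ic50 is None or h is None:
            ic50, h = fit_logistic(curve)
        return float(ic50 * (level / (100.0 - level)) ** (1.0 / h))

    if method != "interp":
        raise ValueError(f"unknown method {method!r}")

    c = curve.concentrations
    inh = curve.inhibition_pct
    exact = np.flatnonzero(np.isclose(inh, level, atol=1e-9))
    if exact.size:
        return float(c[exact[0]])
    # use the cumulative-max envelope so noisy non-monotone wiggles do not
    # produce multiple crossings
    env = np.maximum.accumulate(inh)
    if level > env[-1] or level < env[0]:
        raise ExtrapolationError(
            f"requested IC{level:g} outside observed inhibition range "
            f"[{env[0]:.1f}, {env[-1]:.1f}]%"
        )
    j = int(np.searchsorted(env, level))
    i = j - 1
    c_lo, c_hi = c[i], c[j]
    y_lo, y_hi = env[i], env[j]
    if y_hi == y_lo:
        return float(c_hi)
    t = (level - y_lo) / (y_hi - y_lo)
    if c_lo > 0:
        return float(10 ** (np.log10(c_lo) + t * (np.log10(c_hi) - np.log10(c_lo))))
    return float(c_lo + t * (c_hi - c_lo))


def plot_curve(curve: DoseResponseCurve, path=None):
    """Plot inhibition vs concentration with the logistic fit if present."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.concentrations, curve.inhibition_pct, "o", label="observed")
    if curve.ic50 is not None:
        cc = np.linspace(curve.concentrations.min(), curve.concentrations.max(), 200)
        ax.plot(
            cc,
            100 * (1 - _logistic_growth(cc, curve.ic50, curve.hill_slope)),
            "-",
            label=f"logistic fit (IC50={curve.ic50:.3g})",
        )
    ax.set_xlabel("concentration (mM)")
    ax.set_ylabel("growth inhibition (%)")
    ax.set_title(curve.compound)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
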