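"""Dynamic force spectroscopy: Bell-Evans parameter recovery.

Per-event loading rates are estimated from the terminal slope of each
rising branch; events are pooled into log-spaced loading-rate bins, the
most probable rupture force of each bin is located by a Gaussian kernel
density, and a weighted linear fit of modal force versus log loading rate
yields the zero-force dissociation rate ``k_off`` and the distance to the
transition state ``delta_x``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import gaussian_kde

from .mechanics import KBT_ROOM

__all__ = [
    "LoadingRateBin",
    "BellEvansFit",
    "estimate_loading_rate",
    "bin_by_loading_rate",
    "modal_force",
    "fit_bell_evans",
    "bell_evans_line",
    "plot_dfs",
]


def estimate_loading_rate(
    curve,
    peak,
    terminal_fraction: float = 0.3,
    min_points: int = 10,
) -> float:
    """Loading rate (pN/s) at one rupture from the branch's terminal slope.

    Time is reconstructed from the piezo travel: the cantilever base moves
    at the pulling speed while the tip lags by the deflection, so
    ``t = (extension + force / k_cantilever) / v``.  The rate is the
    end-point derivative of a quadratic fitted to force vs time over the
    last ``terminal_fraction`` of the rising branch - the system stiffens
    as the chain straightens, so an average linear slope over the window
    would systematically understate the rate at rupture.  A flat or
    falling branch returns 0.0.
    """
    meta = curve.metadata
    try:
        v = float(meta["pulling_speed_nm_s"])
        kc = float(meta["cantilever_stiffness_pN_nm"])
    except KeyError as exc:
        raise ValueError(f"curve metadata lacks {exc} needed for loading rate")
    start, stop = peak.branch_start, peak.peak_index
    if stop - start + 1 < min_points:
        raise ValueError("branch too short for a loading-rate estimate")
    n_tail = max(min_points, int(np.ceil((stop - start + 1) * terminal_fraction)))
    sl = slice(max(start, stop + 1 - n_tail), stop + 1)
    f = curve.force[sl]
    t = (curve.extension[sl] + f / kc) / v
    if np.ptp(t) <= 0:
        return 0.0
    t0 = t - t[-1]  # endpoint at 0: the linear coefficient is the end slope
    if f.size >= 3 * min_points:
        slope = float(np.polyfit(t0, f, 2)[1])
    else:
        slope = float(np.polyfit(t0, f, 1)[0])
    return max(slope, 0.0)


@dataclass
class LoadingRateBin:
    """One log-spaced loading-rate bin of a DFS dataset."""

    lower: float
    upper: float
    center: float  # geometric mean of the edges
    forces: np.ndarray
    rates: np.ndarray

    @property
    def n(self) -> int:
        return self.forces.size


def bin_by_loading_rate(
    forces,
    rates,
    n_bins: int = 5,
    rate_range: tuple[float, float] = (1e3, 3e5),
) -> tuple[list[LoadingRateBin], int]:
    """Pool rupture events into log-spaced loading-rate bins.

    Returns the bins (centers at the geometric mean of the edges, matching
    the log-linear Bell-Evans model) and the number of events falling
    outside ``rate_range``.
    """
    forces = np.asarray(forces, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if forces.size == 0 or forces.shape != rates.shape:
        raise ValueError("forces and rates must be equal-length, non-empty")
    lo, hi = rate_range
    edges = np.geomspace(lo, hi, n_bins + 1)
    inside = (rates >= lo) & (rates <= hi)
    n_excluded = int(np.sum(~inside))
    if not np.any(inside):
        raise ValueError("all events fall outside the loading-rate range")
    bins = []
    for i in range(n_bins):
        upper_ok = rates <= edges[i + 1] if i == n_bins - 1 else rates < edges[i + 1]
        mask = inside & (rates >= edges[i]) & upper_ok
        bins.append(
            LoadingRateBin(
                lower=float(edges[i]),
                upper=float(edges[i + 1]),
                center=float(np.sqrt(edges[i] * edges[i + 1])),
                forces=forces[mask],
                rates=rates[mask],
            )
        )
    return bins, n_excluded


def modal_force(
    forces,
    kde_min: int = 20,
    drop_min: int = 5,
    grid_points: int = 512,
) -> float:
    """Most probable rupture force of one bin.

    With at least ``kde_min`` events the mode of a Gaussian kernel density
    (Silverman bandwidth) is returned; between ``drop_min`` and ``kde_min``
    events a histogram mode is used as a fallback; below ``drop_min`` the
    bin is unusable and a ValueError is raised (callers drop the bin with a
    warning).
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size < drop_min:
        raise ValueError(f"bin has {forces.size} events (< {drop_min}); dropped")
    if forces.size >= kde_min and np.ptp(forces) > 0:
        kde = gaussian_kde(forces, bw_method="silverman")
        pad = 3.0 * forces.std(ddof=1) / max(forces.size, 2) ** 0.2
        grid = np.linspace(forces.min() - pad, forces.max() + pad, grid_points)
        return float(grid[np.argmax(kde(grid))])
    counts, edges = np.histogram(forces, bins="auto")
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


@dataclass
class BellEvansFit:
    """Result of the modal-force vs log-loading-rate regression.

    ``slope = kBT / delta_x`` (pN per e-fold of loading rate); the k_off
    uncertainty is multiplicative, so its geometric standard error is
    reported (``k_off */ k_off_geom_se``).
    """

    k_off: float
    delta_x: float
    k_off_geom_se: float
    delta_x_se: float
    slope: float
    intercept: float
    n_bins: int
    thermal_energy: float = KBT_ROOM

    def __post_init__(self) -> None:
        if self.k_off <= 0 or self.delta_x <= 0:
            raise ValueError("k_off and delta_x must be positive")


def fit_bell_evans(
    modal_forces,
    rates,
    thermal_energy: float = KBT_ROOM,
    weights=None,
) -> BellEvansFit:
    """Weighted linear fit of modal force on log loading rate.

    The Bell-Evans relation ``F* = (kBT/dx) ln(r dx / (k_off kBT))`` is
    linear in ``ln r`` with slope ``s = kBT/dx`` and intercept
    ``a = -s ln(s k_off)``, so ``dx = kBT/s`` and ``k_off = exp(-a/s)/s``.
    Standard errors propagate from the regression covariance (delta
    method); the k_off error is reported as a geometric factor.
    """
    f = np.asarray(modal_forces, dtype=float)
    r = np.asarray(rates, dtype=float)
    if f.size != r.size or f.size < 3:
        raise ValueError("need at least 3 (modal force, rate) points")
    if np.any(r <= 0):
        raise ValueError("loading rates must be positive")
    x = sm.add_constant(np.log(r))
    w = np.ones_like(f) if weights is None else np.asarray(weights, dtype=float)
    res = sm.WLS(f, x, weights=w).fit()
    a, s = float(res.params[0]), float(res.params[1])
    if s <= 0:
        raise ValueError("non-positive slope: Bell-Evans fit failed")
    cov = np.asarray(res.cov_params())
    delta_x = thermal_energy / s
    k_off = np.exp(-a / s) / s
    delta_x_se = thermal_energy * np.sqrt(cov[1, 1]) / s**2
    # delta method on ln k_off = -a/s - ln s
    grad = np.array([-1.0 / s, a / s**2 - 1.0 / s])
    var_ln = float(grad @ cov @ grad)
    return BellEvansFit(
        k_off=float(k_off),
        delta_x=float(delta_x),
        k_off_geom_se=float(np.exp(np.sqrt(max(var_ln, 0.0)))),
        delta_x_se=float(delta_x_se),
        slope=s,
        intercept=a,
        n_bins=int(f.size),
        thermal_energy=thermal_energy,
    )


def dfs_from_bins(
    bins: list[LoadingRateBin],
    thermal_energy: float = KBT_ROOM,
    kde_min: int = 20,
    drop_min: int = 5,
) -> BellEvansFit:
    """Modal force per usable bin, then the Bell-Evans fit."""
    modes, centers, weights = [], [], []
    for b in bins:
        try:
            modes.append(modal_force(b.forces, kde_min=kde_min, drop_min=drop_min))
        except ValueError:
            warnings.warn(
                f"bin [{b.lower:.3g}, {b.upper:.3g}] pN/s dropped "
                f"({b.n} events)",
                stacklevel=2,
            )
            continue
        centers.append(b.center)
        weights.append(b.n)
    return fit_bell_evans(modes, centers, thermal_energy, weights=weights)


def bell_evans_line(
    rates, k_off: float, delta_x: float, thermal_energy: float = KBT_ROOM
):
    """Modal force predicted by the Bell-Evans model over a rate grid."""
    r = np.asarray(rates, dtype=float)
    s = thermal_energy / delta_x
    return np.maximum(0.0, s * np.log(r * delta_x / (k_off * thermal_energy)))


def plot_dfs(
    bins: list[LoadingRateBin],
    fit: BellEvansFit,
    path,
    envelope_factor: float = 3.0,
) -> None:
    """Force vs loading-rate plot: events, bin modes, fit and a
    sensitivity envelope (refits with k_off scaled by ``envelope_factor``
    up and down, drawn dashed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for b in bins:
        ax.semilogx(b.rates, b.forces, ".", color="0.7", ms=3)
        if b.n >= 5:
            ax.semilogx([b.center], [modal_force(b.forces)], "kD", ms=6)
    grid = np.geomspace(min(b.lower for b in bins), max(b.upper for b in bins), 100)
    ax.semilogx(grid, bell_evans_line(grid, fit.k_off, fit.delta_x,
                                      fit.thermal_energy), "k-")
    for factor in (envelope_factor, 1.0 / envelope_factor):
        ax.semilogx(
            grid,
            bell_evans_line(grid, fit.k_off * factor, fit.delta_x,
                            fit.thermal_energy),
            "k--", lw=0.8,
        )
    ax.set_xlabel("loading rate (pN/s)")
    ax.set_ylabel("rupture force (pN)")
    ax.set_title(
        f"k_off = {fit.k_off:.3g} 1/s, dx = {fit.delta_x:.3g} nm"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
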