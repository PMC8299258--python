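"""Polymer elasticity and forced bond-rupture kinetics.

This module provides the physics shared by the pulling simulator and the
curve analysis pipeline:

* the Marko-Siggia interpolation of the worm-like chain (WLC), which maps
  the fractional extension of an unfolded polypeptide to the entropic
  restoring force, and its numerical inverse;
* contour-length algebra: the contour increment released when a folded
  segment of ``n`` residues with folded end-to-end distance ``d`` unravels
  is ``0.36 nm/aa * n - d``;
* Bell-Evans kinetics of force-induced bond rupture,
  ``k(F) = k_off * exp(F * dx / kBT)``, the most probable rupture force at
  a constant loading rate, and exact inverse-CDF sampling of rupture
  forces from the Bell-Evans distribution.

All lengths are in nm, forces in pN, energies in pN nm, rates in 1/s and
loading rates in pN/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "KBT_ROOM",
    "RESIDUE_LENGTH",
    "WlcParameters",
    "KineticParameters",
    "SegmentEntry",
    "SegmentTable",
    "wlc_force",
    "wlc_stiffness",
    "wlc_extension",
    "contour_increment",
    "bell_rate",
    "most_probable_force",
    "sample_rupture_force",
    "rupture_force_cdf",
    "calibrate_koff",
    "effective_loading_rate",
]

#: Thermal energy at 298 K in pN nm.
KBT_ROOM = 4.114

#: Contour length gained per amino acid in nm.
RESIDUE_LENGTH = 0.36


@dataclass(frozen=True)
class WlcParameters:
    """Worm-like chain parameters.

    persistence_length
        Persistence length ``p`` in nm.  0.4 nm is a typical value for an
        unfolded polypeptide stretched in an AFM experiment.
    thermal_energy
        ``kBT`` in pN nm (4.114 at 298 K).
    """

    persistence_length: float = 0.4
    thermal_energy: float = KBT_ROOM

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if self.thermal_energy <= 0:
            raise ValueError("thermal_energy must be positive")


@dataclass(frozen=True)
class KineticParameters:
    """Bell-Evans parameters of a rupturable bond or folded domain.

    k_off
        Spontaneous (zero-force) dissociation rate in 1/s.
    delta_x
        Distance from the bound state to the transition state along the
        pulling coordinate, in nm.
    """

    k_off: float
    delta_x: float

    def __post_init__(self) -> None:
        if self.k_off <= 0:
            raise ValueError("k_off must be positive")
        if self.delta_x <= 0:
            raise ValueError("delta_x must be positive")


DEFAULT_WLC = WlcParameters()


def _wlc_params(params: WlcParameters | None) -> WlcParameters:
    return DEFAULT_WLC if params is None else params


def wlc_force(extension, contour_length: float, params: WlcParameters | None = None):
    """Marko-Siggia worm-like chain force at a given extension.

    ``F = (kBT/p) * [1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc]``

    Accepts scalar or array ``extension``; requires ``0 <= x < Lc``.
    """
    params = _wlc_params(params)
    if contour_length <= 0:
        raise ValueError("contour_length must be positive")
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be non-negative")
    if np.any(x >= contour_length):
        raise ValueError("extension must be below the contour length")
    t = x / contour_length
    f = (params.thermal_energy / params.persistence_length) * (
        0.25 / (1.0 - t) ** 2 - 0.25 + t
    )
    return f if f.ndim else float(f)


def wlc_stiffness(extension, contour_length: float, params: WlcParameters | None = None):
    """Derivative dF/dx of the Marko-Siggia force, in pN/nm."""
    params = _wlc_params(params)
    if contour_length <= 0:
        raise ValueError("contour_length must be positive")
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0) or np.any(x >= contour_length):
        raise ValueError("extension out of [0, contour_length)")
    t = x / contour_length
    k = (params.thermal_energy / params.persistence_length) * (
        0.5 / (1.0 - t) ** 3 + 1.0
    ) / contour_length
    return k if k.ndim else float(k)


def _relative_extension_of_force(force: float, params: WlcParameters) -> float:
    """Solve the reduced Marko-Siggia relation for t = x/Lc at a given force."""
    if force < 0:
        raise ValueError("force must be non-negative")
    if force == 0.0:
        return 0.0
    fred = force * params.persistence_length / params.thermal_energy

    def g(t: float) -> float:
        return 0.25 / (1.0 - t) ** 2 - 0.25 + t - fred

    return brentq(g, 0.0, 1.0 - 1e-12, xtol=1e-14, rtol=8.9e-16)


def wlc_extension(force, contour_length: float, params: WlcParameters | None = None):
    """Numerical inverse of :func:`wlc_force`: extension at a given force.

    The returned extension lies in ``[0, Lc)`` and round-trips through
    :func:`wlc_force` to well below 1e-6 pN.
    """
    params = _wlc_params(params)
    if contour_length <= 0:
        raise ValueError("contour_length must be positive")
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    if f.ndim == 0:
        return _relative_extension_of_force(float(f), params) * contour_length
    t = np.array([_relative_extension_of_force(v, params) for v in f.ravel()])
    return (t * contour_length).reshape(f.shape)


def contour_increment(
    n_aa: int, folded_distance: float, residue_length: float = RESIDUE_LENGTH
) -> float:
    """Contour-length increment released by unfolding a segment.

    ``dLc = residue_length * n_aa - folded_distance`` - e.g. the 34-residue
    metallothionein alpha-domain segment with a 1.3 nm folded end-to-end
    distance releases 0.36*34 - 1.3 = 10.94 nm (reported as 10.9 nm).
    """
    if n_aa < 0:
        raise ValueError("n_aa must be non-negative")
    if folded_distance < 0:
        raise ValueError("folded_distance must be non-negative")
    dlc = residue_length * n_aa - folded_distance
    if n_aa > 0 and dlc <= 0:
        warnings.warn(
            "segment contour increment is non-positive: folded distance "
            "exceeds the stretched segment length",
            stacklevel=2,
        )
    return dlc


@dataclass(frozen=True)
class SegmentEntry:
    """One protein segment: residue count, folded end-to-end distance and
    the theoretical contour increment its unfolding releases."""

    label: str
    n_aa: int
    folded_distance: float
    theoretical_dlc: float


@dataclass
class SegmentTable:
    """Table of segment definitions anchored at metal-binding cysteines.

    Residue counts are stored verbatim as published rather than derived
    from residue indices: the printed counts do not follow a single
    inclusive/exclusive endpoint convention, so index arithmetic would
    silently disagree with the tabulated increments.
    """

    entries: list[SegmentEntry] = field(default_factory=list)
    residue_length: float = RESIDUE_LENGTH

    def __post_init__(self) -> None:
        for e in self.entries:
            expected = self.residue_length * e.n_aa - e.folded_distance
            if abs(expected - e.theoretical_dlc) > 1e-6:
                raise ValueError(
                    f"segment {e.label!r}: theoretical_dlc {e.theoretical_dlc} "
                    f"inconsistent with {self.residue_length}*{e.n_aa} - "
                    f"{e.folded_distance} = {expected}"
                )
            if e.theoretical_dlc <= 0:
                raise ValueError(f"segment {e.label!r}: non-positive increment")

    @classmethod
    def from_counts(
        cls,
        rows: list[tuple[str, int, float]],
        residue_length: float = RESIDUE_LENGTH,
    ) -> "SegmentTable":
        entries = [
            SegmentEntry(label, n, d, contour_increment(n, d, residue_length))
            for label, n, d in rows
        ]
        return cls(entries=entries, residue_length=residue_length)

    @classmethod
    def default(cls) -> "SegmentTable":
        """Metallothionein-III segment table.

        Folded distances for the two alpha sub-segments (0.72 and 0.42 nm)
        are back-calculated so that the table reproduces the published
        theoretical increments (3.6 and 7.5 nm); the full-domain distances
        (1.3 nm alpha, 1.2 nm beta) are the published folded cysteine
        separations.
        """
        return cls.from_counts(
            [
                ("alpha:Cys34-Cys67", 34, 1.3),  # 10.94 nm, full M4S11 segment
                ("alpha:Cys34-Cys45", 12, 0.72),  # 3.6 nm, N-terminal sub-segment
                ("alpha:Cys45-Cys67", 22, 0.42),  # 7.5 nm, C-terminal sub-segment
                ("alpha:Cys51-Cys64-free", 13, 0.18),  # ~4.5 nm cysteine-free stretch
                ("beta:Cys6-Cys30", 25, 1.2),  # 7.8 nm, full M3S9 segment
            ]
        )

    def get(self, label: str) -> SegmentEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            [
                {
                    "label": e.label,
                    "n_aa": e.n_aa,
                    "folded_distance_nm": e.folded_distance,
                    "theoretical_dlc_nm": e.theoretical_dlc,
                }
                for e in self.entries
            ]
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path, residue_length: float = RESIDUE_LENGTH) -> "SegmentTable":
        df = pd.read_csv(path, sep="\t")
        entries = [
            SegmentEntry(
                str(r.label),
                int(r.n_aa),
                float(r.folded_distance_nm),
                float(r.theoretical_dlc_nm),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(entries=entries, residue_length=residue_length)


# ---------------------------------------------------------------------------
# Bell-Evans kinetics


def bell_rate(force, params: KineticParameters, thermal_energy: float = KBT_ROOM):
    """Force-dependent rupture rate ``k(F) = k_off exp(F dx / kBT)``."""
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    arg = np.minimum(f * params.delta_x / thermal_energy, 700.0)
    k = params.k_off * np.exp(arg)
    return k if k.ndim else float(k)


def most_probable_force(
    loading_rate: float, params: KineticParameters, thermal_energy: float = KBT_ROOM
) -> float:
    """Mode of the Bell-Evans rupture-force distribution at constant loading rate.

    ``F* = (kBT/dx) ln(r dx / (k_off kBT))``, clipped at zero: at very low
    loading rates the formal mode is negative, but a physical rupture force
    is non-negative and the dynamic-force-spectroscopy fit never operates
    there.
    """
    if loading_rate <= 0:
        raise ValueError("loading_rate must be positive")
    scale = thermal_energy / params.delta_x
    f = scale * np.log(loading_rate * params.delta_x / (params.k_off * thermal_energy))
    return max(0.0, float(f))


def sample_rupture_force(
    loading_rate: float,
    params: KineticParameters,
    thermal_energy: float = KBT_ROOM,
    rng=None,
    size=None,
):
    """Draw rupture forces from the Bell-Evans distribution by inverse CDF.

    The survival function under a constant loading rate ``r`` is
    ``S(F) = exp[-(k_off kBT / (r dx)) (exp(F dx / kBT) - 1)]``; with an
    exponential deviate ``E`` the exact inverse is
    ``F = (kBT/dx) log1p(r dx E / (k_off kBT))``.

    ``rng`` may be an integer seed or a ``numpy.random.Generator``; a fixed
    seed yields an identical sample sequence.
    """
    if loading_rate <= 0:
        raise ValueError("loading_rate must be positive")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    e = rng.exponential(size=size)
    scale = thermal_energy / params.delta_x
    coef = loading_rate * params.delta_x / (params.k_off * thermal_energy)
    f = scale * np.log1p(coef * e)
    return f if size is not None else float(f)


def rupture_force_cdf(
    force,
    loading_rate: float,
    params: KineticParameters,
    thermal_energy: float = KBT_ROOM,
):
    """Analytic CDF of the Bell-Evans rupture-force distribution."""
    f = np.asarray(force, dtype=float)
    coef = params.k_off * thermal_energy / (loading_rate * params.delta_x)
    c = 1.0 - np.exp(-coef * np.expm1(f * params.delta_x / thermal_energy))
    return c if c.ndim else float(c)


def calibrate_koff(
    target_force: float,
    loading_rate: float,
    delta_x: float,
    thermal_energy: float = KBT_ROOM,
) -> float:
    """Solve for the k_off that puts the Bell-Evans modal force at a target.

    Inverts ``F* = (kBT/dx) ln(r dx/(k_off kBT))`` for ``k_off``.  Used to
    parameterize marker domains whose rupture force, but not rate, is known.
    """
    if target_force <= 0 or loading_rate <= 0 or delta_x <= 0:
        raise ValueError("target_force, loading_rate and delta_x must be positive")
    return (
        loading_rate
        * delta_x
        / (thermal_energy * np.exp(target_force * delta_x / thermal_energy))
    )


def effective_loading_rate(
    force: float,
    contour_length: float,
    wlc: WlcParameters | None = None,
    cantilever_stiffness: float = 40.0,
    pulling_speed: float = 3000.0,
) -> float:
    """Loading rate of the WLC-cantilever series at a given force.

    ``r = k_eff * v`` with ``1/k_eff = 1/k_wlc(F) + 1/k_cantilever``.  This
    is the analytic oracle for per-event loading-rate estimates from
    constant-velocity curves.
    """
    wlc = _wlc_params(wlc)
    x = wlc_extension(force, contour_length, wlc)
    kw = wlc_stiffness(x, contour_length, wlc)
    keff = 1.0 / (1.0 / kw + 1.0 / cantilever_stiffness)
    return keff * pulling_speed
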