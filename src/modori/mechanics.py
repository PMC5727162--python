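"""Torsional-spring hinge + worm-like-chain adjuster mechanics.

The hinged bundle is modelled as two rigid arms joined by a harmonic
torsional spring (stiffness ``k``, rest angle ``theta0``, default 180 deg for
a straight-folding reference), loaded by the entropic tension of the ssDNA
adjuster spanning the arms as a chord.  The adjuster follows the Marko-Siggia
worm-like-chain interpolation.  The equilibrium included angle is the
minimum of the total strain energy

    E(theta) = 1/2 k (theta - theta0)^2 + E_wlc(x(theta)),

with the chord extension x(theta) given by the law of cosines from the
anchor distances ``r1``, ``r2``.  Conversely, a measured angle and adjuster
length determine the hinge stiffness through the torque balance

    k (theta0 - theta) = F_wlc(x) * r1 r2 sin(theta) / x,

which is exactly the stationarity condition of E, so prediction and
estimation are mutually consistent by construction.

A duplex adjuster is treated as a rigid strut: it sets the chord length
geometrically (0.34 nm/bp) and the included angle becomes independent of the
hinge stiffness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .design import DUPLEX_RISE_NM, SINGLE_RISE_NM

#: thermal energy at 298 K, pN nm
KT_PN_NM = 4.114
#: default ssDNA persistence length (high-Mg regime), nm
SS_PERSISTENCE_NM = 1.0
#: distance from the hinge pivot to each adjuster anchor in the default
#: reference geometry (252 nt of duplex arm on either side), nm
DEFAULT_ANCHOR_NT = 252


class MechanicsError(ValueError):
    pass


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters of the ssDNA adjuster."""
    persistence_nm: float
    contour_nm: float
    kT: float = KT_PN_NM

    def __post_init__(self):
        if min(self.persistence_nm, self.contour_nm, self.kT) <= 0:
            raise MechanicsError("WLC parameters must be positive")

    @classmethod
    def for_ss_adjuster(cls, n_nt: int, persistence_nm: float = SS_PERSISTENCE_NM,
                        kT: float = KT_PN_NM) -> "WLCParams":
        return cls(persistence_nm, n_nt * SINGLE_RISE_NM, kT)


@dataclass(frozen=True)
class TorsionalHinge:
    stiffness: float  # pN nm / rad
    rest_angle_deg: float = 180.0

    def __post_init__(self):
        if self.stiffness < 0:
            raise MechanicsError("stiffness must be non-negative")
        if not 0.0 < self.rest_angle_deg <= 180.0:
            raise MechanicsError("rest angle must lie in (0, 180] degrees")


@dataclass(frozen=True)
class HingeGeometry:
    """Distances from the hinge pivot to the adjuster anchors, nm."""
    r1: float = DEFAULT_ANCHOR_NT * DUPLEX_RISE_NM
    r2: float = DEFAULT_ANCHOR_NT * DUPLEX_RISE_NM

    def __post_init__(self):
        if min(self.r1, self.r2) <= 0:
            raise MechanicsError("anchor distances must be positive")


@dataclass(frozen=True)
class EnergyLandscape:
    theta_deg: np.ndarray
    e_hinge: np.ndarray
    e_adjuster: np.ndarray
    feasible: np.ndarray  # extension < contour length

    @property
    def e_total(self) -> np.ndarray:
        return self.e_hinge + self.e_adjuster

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta_deg": self.theta_deg,
                             "E_hinge": self.e_hinge,
                             "E_adjuster": self.e_adjuster,
                             "E_total": self.e_total,
                             "feasible": self.feasible})


@dataclass(frozen=True)
class AngleObservation:
    adjuster_length_nt: int
    mean_angle_deg: float
    sd_deg: float = 0.0
    n: int = 1

    def __post_init__(self):
        if not 0.0 <= self.mean_angle_deg <= 180.0:
            raise MechanicsError("mean angle must lie in [0, 180] degrees")
        if self.n < 1:
            raise MechanicsError("observation count must be >= 1")


@dataclass(frozen=True)
class StiffnessEstimate:
    per_observation: tuple[float, ...]
    skipped: tuple[AngleObservation, ...] = ()

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_observation))

    @property
    def min(self) -> float:
        return float(np.min(self.per_observation))

    @property
    def max(self) -> float:
        return float(np.max(self.per_observation))


# ---------------------------------------------------------------------------
# worm-like chain

def wlc_force(x, params: WLCParams):
    """Marko-Siggia entropic tension (pN) at end-to-end extension x (nm).

    F = (kT/Lp) [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ]
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= params.contour_nm):
        raise MechanicsError("extension must satisfy 0 <= x < contour length")
    t = x / params.contour_nm
    f = (params.kT / params.persistence_nm) * (0.25 / (1 - t) ** 2 - 0.25 + t)
    return f if f.ndim else float(f)


def wlc_energy(x, params: WLCParams):
    """Stretching energy (pN nm): closed-form integral of the Marko-Siggia
    force from 0 to x, so E(0) = 0 and dE/dx = F."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= params.contour_nm):
        raise MechanicsError("extension must satisfy 0 <= x < contour length")
    lc = params.contour_nm
    t = x / lc
    e = (params.kT / params.persistence_nm) * (
        lc * 0.25 / (1 - t) - lc * 0.25 - x * 0.25 + x ** 2 / (2 * lc))
    return e if e.ndim else float(e)


def adjuster_extension(theta_deg, geom: HingeGeometry):
    """Chord length between the adjuster anchors at included angle theta:
    x = sqrt(r1^2 + r2^2 - 2 r1 r2 cos theta)."""
    th = np.radians(np.asarray(theta_deg, dtype=float))
    x2 = geom.r1 ** 2 + geom.r2 ** 2 - 2 * geom.r1 * geom.r2 * np.cos(th)
    x = np.sqrt(np.maximum(x2, 0.0))
    return x if x.ndim else float(x)


# ---------------------------------------------------------------------------
# strain-energy landscape

def energy_landscape(hinge: TorsionalHinge, geom: HingeGeometry,
                     wlc: WLCParams,
                     theta_deg: np.ndarray | None = None) -> EnergyLandscape:
    """Total strain energy over a grid of included angles.

    Deformation outside the hinge and adjuster is neglected.  Grid points
    where the required chord exceeds the adjuster contour length are flagged
    infeasible (energies set to +inf there).
    """
    if theta_deg is None:
        theta_deg = np.arange(0.05, 180.0 + 1e-9, 0.05)
    theta_deg = np.asarray(theta_deg, dtype=float)
    x = adjuster_extension(theta_deg, geom)
    feasible = x < wlc.contour_nm * (1 - 1e-9)
    th = np.radians(theta_deg)
    e_h = 0.5 * hinge.stiffness * (th - math.radians(hinge.rest_angle_deg)) ** 2
    e_a = np.full_like(theta_deg, np.inf)
    if feasible.any():
        e_a[feasible] = wlc_energy(x[feasible], wlc)
    e_h = np.where(feasible, e_h, np.inf)
    return EnergyLandscape(theta_deg, e_h, e_a, feasible)


def predict_angle(hinge: TorsionalHinge, geom: HingeGeometry,
                  wlc: WLCParams, tol_deg: float = 1e-4) -> float:
    """Equilibrium included angle: the minimiser of the total strain energy,
    located by a bracketing grid plus bounded refinement.  Ties are broken
    towards the rest angle."""
    grid = energy_landscape(hinge, geom, wlc,
                            np.arange(0.05, 180.0 + 1e-9, 0.05))
    e = grid.e_total
    if not grid.feasible.any():
        raise MechanicsError("no feasible included angle for this adjuster")
    # tie-break towards theta0
    candidates = np.flatnonzero(e <= e.min() + 1e-12)
    i = candidates[np.argmin(np.abs(grid.theta_deg[candidates]
                                    - hinge.rest_angle_deg))]
    lo = grid.theta_deg[max(i - 1, 0)]
    hi = grid.theta_deg[min(i + 1, len(e) - 1)]
    if not (grid.feasible[max(i - 1, 0)] and grid.feasible[min(i + 1, len(e) - 1)]):
        return float(grid.theta_deg[i])

    def objective(t):
        x = adjuster_extension(t, geom)
        if x >= wlc.contour_nm:
            return np.inf
        return (0.5 * hinge.stiffness
                * (math.radians(t) - math.radians(hinge.rest_angle_deg)) ** 2
                + wlc_energy(x, wlc))

    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": tol_deg / 10})
    theta = float(res.x)
    if objective(theta) > e[i]:
        theta = float(grid.theta_deg[i])
    return theta


def predict_angle_ds(adjuster_length_nt: int, geom: HingeGeometry) -> float:
    """Included angle set geometrically by a duplex (strut-bound) adjuster:
    the chord 0.34 n must match the anchor separation.  Independent of the
    hinge stiffness by construction."""
    x = adjuster_length_nt * DUPLEX_RISE_NM
    lo, hi = abs(geom.r1 - geom.r2), geom.r1 + geom.r2
    if x > hi + 1e-9:
        raise MechanicsError(
            f"duplex adjuster of {adjuster_length_nt} nt ({x:.1f} nm) cannot "
            f"span anchors {hi:.1f} nm apart")
    if x <= lo:
        return 0.0
    c = (geom.r1 ** 2 + geom.r2 ** 2 - x ** 2) / (2 * geom.r1 * geom.r2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def boltzmann_stats(landscape: EnergyLandscape, kT: float = KT_PN_NM
                    ) -> tuple[float, float]:
    """Thermal mean and standard deviation (degrees) of the included angle
    under p(theta) proportional to exp(-E_total/kT) on the landscape grid."""
    feas = landscape.feasible
    if not feas.any():
        raise MechanicsError("landscape has no feasible grid points")
    th = landscape.theta_deg[feas]
    e = landscape.e_total[feas]
    w = np.exp(-(e - e.min()) / kT)
    w /= w.sum()
    mean = float(np.sum(w * th))
    sd = float(np.sqrt(np.sum(w * (th - mean) ** 2)))
    return mean, sd


# ---------------------------------------------------------------------------
# stiffness estimation

def stiffness_from_observation(theta_deg: float, geom: HingeGeometry,
                               wlc: WLCParams,
                               rest_angle_deg: float = 180.0) -> float:
    """Torsional stiffness from one equilibrium angle via torque balance:
    k (theta0 - theta) = F(x) r1 r2 sin(theta) / x."""
    if abs(theta_deg - rest_angle_deg) < 1e-9:
        raise MechanicsError(
            "angle equals the rest angle: stiffness is indeterminate")
    x = adjuster_extension(theta_deg, geom)
    if x >= wlc.contour_nm:
        raise MechanicsError("observation implies an over-stretched adjuster")
    torque = wlc_force(x, wlc) * geom.r1 * geom.r2 * math.sin(
        math.radians(theta_deg)) / x
    return torque / math.radians(rest_angle_deg - theta_deg)


def estimate_stiffness(observations: list[AngleObservation],
                       geom: HingeGeometry,
                       wlc_for: "callable | None" = None,
                       rest_angle_deg: float = 180.0) -> StiffnessEstimate:
    """Per-observation torque-balance stiffnesses, aggregated as mean with
    min/max spread.  Observations with a slack adjuster (chord shorter than
    needed to develop tension is impossible for WLC, but an over-stretched
    one is) are skipped; an observation at the rest angle is an error."""
    if wlc_for is None:
        wlc_for = WLCParams.for_ss_adjuster
    ks, skipped = [], []
    for obs in observations:
        wlc = wlc_for(obs.adjuster_length_nt)
        if abs(obs.mean_angle_deg - rest_angle_deg) < 1e-9:
            raise MechanicsError(
                f"observation at the rest angle ({rest_angle_deg} deg): "
                "zero deflection, stiffness indeterminate")
        x = adjuster_extension(obs.mean_angle_deg, geom)
        if x >= wlc.contour_nm:
            skipped.append(obs)
            continue
        ks.append(stiffness_from_observation(obs.mean_angle_deg, geom, wlc,
                                             rest_angle_deg))
    if not ks:
        raise MechanicsError("no usable observations")
    return StiffnessEstimate(tuple(ks), tuple(skipped))


def observations_from_csv(path) -> list[AngleObservation]:
    df = pd.read_csv(path)
    return [AngleObservation(int(r.adjuster_nt), float(r.mean_angle_deg),
                             float(getattr(r, "sd_deg", 0.0)),
                             int(getattr(r, "n", 1)))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# PCA / equipartition stiffness

def pca_stiffness(trajectory, kT: float = KT_PN_NM):
    """Equipartition stiffness from an angle trajectory.

    For a 1-D trajectory of included angles (degrees), k = kT / var(theta)
    with theta in radians after mean removal.  For multivariate input
    (n_samples x n_modes), a PCA is performed and one stiffness per principal
    mode is returned, k_i = kT / lambda_i (ascending in mode order, since
    eigenvalues are sorted descending).  Zero variance yields +inf.
    """
    arr = np.radians(np.asarray(trajectory, dtype=float))
    if arr.ndim == 1:
        if arr.size < 100:
            raise MechanicsError("trajectory must have at least 100 samples")
        var = float(np.var(arr - arr.mean()))
        return math.inf if var == 0 else kT / var
    if arr.shape[0] < 100:
        raise MechanicsError("trajectory must have at least 100 samples")
    centered = arr - arr.mean(axis=0)
    cov = np.cov(centered, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    with np.errstate(divide="ignore"):
        return np.where(evals > 0, kT / np.maximum(evals, 1e-300), np.inf)
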