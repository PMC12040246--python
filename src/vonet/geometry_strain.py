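"""Thin-walled-sphere left-ventricular geometry and the strain input mapping.

The left ventricle is idealized as a thin-walled sphere. End-diastolic
myofiber stretch follows from cavity volumes,

    lambda = (V_ED / V0)^(1/3),

with V0 the unloaded (zero-pressure) cavity volume, and strain is the
Lagrangian strain relative to the unloaded state,

    eps_f = (lambda^2 - 1) / 2.

Eccentric growth (series sarcomere addition) enlarges the unloaded sphere:
under the default constant-wall-thickness rule, wall mass scales with r0^2,
so a mass fold change m implies a V0 fold change of m^(3/2). Growth thereby
lowers the stretch produced by any given end-diastolic volume — the
feedback between growth and the mechanical growth stimulus.

Organ-scale strain drives the signaling network through an exponential map

    w_myoStrain = Cmyo * (exp(Dmyo * eps_f / eps_f0) - 1),

anchored so that the unloaded state gives zero input and the pre-overload
baseline strain eps_f0 gives the prescribed baseline weight w0; Dmyo is not
free but solved from (Cmyo, w0) as Dmyo = ln(1 + w0/Cmyo).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "SphericalGeometry",
    "StrainCurve",
    "MyoStrainMap",
    "stretch_from_volumes",
    "lagrangian_strain",
    "stretch_from_strain",
    "unloaded_volume_fold",
    "strain_trajectory",
    "solve_dmyo",
]


@dataclass(frozen=True)
class SphericalGeometry:
    """Unloaded cavity volume and baseline end-diastolic fiber stretch."""

    v0: float = 1.0
    lambda_ed0: float = 1.12

    def __post_init__(self):
        if self.v0 <= 0:
            raise ValueError(f"V0 must be positive, got {self.v0}")
        if self.lambda_ed0 < 1.0:
            raise ValueError(f"lambda_ed0 must be >= 1, got {self.lambda_ed0}")

    @property
    def eps_f0(self) -> float:
        return lagrangian_strain(self.lambda_ed0)


def stretch_from_volumes(v_ed, v0):
    """Circumferential stretch of a sphere inflated from V0 to V_ED."""
    v_ed = np.asarray(v_ed, dtype=float)
    if np.any(v_ed <= 0) or np.any(np.asarray(v0, dtype=float) <= 0):
        raise ValueError("volumes must be positive")
    out = (v_ed / v0) ** (1.0 / 3.0)
    return out if out.ndim else float(out)


def lagrangian_strain(lam):
    """Lagrangian strain eps_f = (lambda^2 - 1)/2 relative to the unloaded state."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    out = 0.5 * (lam**2 - 1.0)
    return out if out.ndim else float(out)


def stretch_from_strain(eps_f):
    """Inverse of :func:`lagrangian_strain` (requires eps_f > -1/2)."""
    eps_f = np.asarray(eps_f, dtype=float)
    if np.any(eps_f <= -0.5):
        raise ValueError("Lagrangian strain must exceed -1/2")
    out = np.sqrt(2.0 * eps_f + 1.0)
    return out if out.ndim else float(out)


def unloaded_volume_fold(lvm_fold, exponent: float = 1.5):
    """Unloaded-volume fold change implied by an LV-mass fold change.

    Default rule: a thin sphere with constant wall thickness has wall mass
    proportional to r0^2, so V0 ∝ r0^3 ∝ mass^(3/2). The exponent is
    exposed so alternative growth rules can be substituted.
    """
    lvm_fold = np.asarray(lvm_fold, dtype=float)
    if np.any(lvm_fold <= 0):
        raise ValueError("mass fold change must be positive")
    out = lvm_fold**exponent
    return out if out.ndim else float(out)


@dataclass
class StrainCurve:
    """End-diastolic stretch and strain on a t/tau grid."""

    times: np.ndarray
    lam: np.ndarray
    eps_f: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        """Linear interpolation of eps_f at t (t/tau units)."""
        out = np.interp(np.asarray(t, dtype=float), self.times, self.eps_f)
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_over_tau": self.times, "lambda": self.lam, "eps_f": self.eps_f}
        )


def strain_trajectory(
    times: np.ndarray,
    fc_ved: np.ndarray | Callable[[np.ndarray], np.ndarray],
    fc_lvm: np.ndarray | Callable[[np.ndarray], np.ndarray],
    lambda_ed0: float,
    v0_rule: Callable[[np.ndarray], np.ndarray] = unloaded_volume_fold,
) -> StrainCurve:
    """End-diastolic strain over time from volume and mass fold-change curves.

    ``lambda(t) = lambda_ed0 * (fc_VED(t) / V0fold(fc_LVM(t)))^(1/3)`` with
    the fold curves anchored at 1 at t = 0, so eps_f(0) equals the baseline
    strain implied by ``lambda_ed0``.
    """
    times = np.asarray(times, dtype=float)
    ved = np.asarray(fc_ved(times) if callable(fc_ved) else fc_ved, dtype=float)
    lvm = np.asarray(fc_lvm(times) if callable(fc_lvm) else fc_lvm, dtype=float)
    if ved.shape != times.shape or lvm.shape != times.shape:
        raise ValueError(
            f"fold curves must align with the time grid: times {times.shape}, "
            f"VED {ved.shape}, LVM {lvm.shape}"
        )
    lam = lambda_ed0 * (ved / v0_rule(lvm)) ** (1.0 / 3.0)
    return StrainCurve(times=times, lam=lam, eps_f=lagrangian_strain(lam))


def solve_dmyo(cmyo: float, w0: float, eps_f0: float = None) -> float:
    """Exponent coefficient making the strain map hit w0 at baseline strain.

    Inverts the exponential map at eps_f = eps_f0: Dmyo = ln(1 + w0/Cmyo).
    (eps_f0 cancels out of the inversion; it is accepted for signature
    symmetry with the map itself.)
    """
    if cmyo <= 0:
        raise ValueError(f"Cmyo must be positive, got {cmyo}")
    if w0 < 0:
        raise ValueError(f"baseline weight must be nonnegative, got {w0}")
    return math.log(1.0 + w0 / cmyo)


@dataclass(frozen=True)
class MyoStrainMap:
    """Exponential map from organ-scale strain to the network's strain input.

    ``w(eps_f) = Cmyo (e^{Dmyo eps_f / eps_f0} - 1)``: zero at zero strain
    (fully unloaded ventricle), w0 at baseline strain, strictly increasing.
    For eps_f < 0 the same formula applies, giving small negative values
    floored at -Cmyo(1 - e^{-Dmyo|eps_f|/eps_f0}); callers clip the network
    weight at zero.
    """

    cmyo: float
    dmyo: float
    w0: float
    eps_f0: float

    @classmethod
    def solve(cls, cmyo: float, w0: float, eps_f0: float) -> "MyoStrainMap":
        if eps_f0 <= 0:
            raise ValueError(f"baseline strain must be positive, got {eps_f0}")
        return cls(cmyo=cmyo, dmyo=solve_dmyo(cmyo, w0), w0=w0, eps_f0=eps_f0)

    def __call__(self, eps_f):
        eps_f = np.asarray(eps_f, dtype=float)
        out = self.cmyo * np.expm1(self.dmyo * eps_f / self.eps_f0)
        return out if out.ndim else float(out)
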