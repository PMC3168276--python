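"""Angiogenic activity measure and regime classification.

The local balance between the nondimensional proangiogenic and
antiangiogenic concentrations is summarized by the antisymmetric measure

    a = f̃_p/f̃_a − 1   if f̃_p ≥ f̃_a,
    a = 1 − f̃_a/f̃_p   if f̃_p < f̃_a,

so a > 0 where new-vessel growth is being initiated, a = 0 at perfect
balance (stable vasculature) and a < 0 where angiogenesis is suppressed.
Within the tumor (r̃ ∈ [0, 1]) the sign pattern of a defines the regime:
negative everywhere = global suppression, positive everywhere = global
angiogenesis, and the classic necrotic-core phenotype — negative at the
core, positive toward the rim — is focal suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agf import FactorField

__all__ = [
    "ActivityProfile",
    "activity",
    "classify_regime",
    "activity_profile",
    "REGIMES",
]

REGIMES = ("focal_suppression", "global_suppression", "global_angiogenesis", "mixed")

#: Sign tolerance on a for classification: |a| below this counts as balanced,
#: guarding against floating-point flutter near the exact balance point.
DEFAULT_TOL = 1e-6


@dataclass(frozen=True)
class ActivityProfile:
    """Activity a(r̃) inside the tumor (r̃ ∈ [0, 1]) and its regime label."""

    r_grid: np.ndarray
    a: np.ndarray
    regime: str

    @property
    def peak(self) -> float:
        return float(np.max(self.a))

    @property
    def peak_location(self) -> float:
        return float(self.r_grid[int(np.argmax(self.a))])

    def stimulated_fraction(self, tol: float = DEFAULT_TOL) -> float:
        """r̃²-weighted volume fraction of the tumor where a > tol.

        Trapezoidal integral of the indicator against r̃² — the natural
        measure of "how much of the tumor is angiogenically stimulated".
        """
        w = np.where(self.a > tol, 1.0, 0.0) * self.r_grid**2
        total = np.trapezoid(self.r_grid**2, self.r_grid)
        return float(np.trapezoid(w, self.r_grid) / total)


def activity(f_p, f_a):
    """Angiogenic activity of pro/anti concentration(s); scalar or array.

    Antisymmetric in its arguments (a(x, y) = −a(y, x)), zero at balance,
    strictly increasing in f_p.  Inputs must be strictly positive.
    """
    f_p = np.asarray(f_p, dtype=float)
    f_a = np.asarray(f_a, dtype=float)
    if np.any(f_p <= 0) or np.any(f_a <= 0):
        raise ValueError("factor concentrations must be strictly positive")
    a = np.where(f_p >= f_a, f_p / f_a - 1.0, 1.0 - f_a / f_p)
    return a if a.ndim else float(a)


def classify_regime(a: np.ndarray, tol: float = DEFAULT_TOL) -> str:
    """Regime label for an activity profile sampled on [0, 1].

    ``global_angiogenesis`` if a > tol everywhere, ``global_suppression`` if
    a < −tol everywhere, ``focal_suppression`` if the core (r̃ = 0) is
    suppressed but some interior/rim point is stimulated, ``mixed`` for any
    other sign pattern (e.g. stimulated core with suppressed rim).
    """
    a = np.asarray(a, dtype=float)
    if np.all(a > tol):
        return "global_angiogenesis"
    if np.all(a < -tol):
        return "global_suppression"
    if a[0] < -tol and np.any(a[1:] > tol):
        return "focal_suppression"
    return "mixed"


def activity_profile(field: FactorField, tol: float = DEFAULT_TOL) -> ActivityProfile:
    """Activity and regime of a solved factor field, restricted to the tumor."""
    J = field.interface_index
    r = field.r_grid[: J + 1]
    a = activity(field.f_p[: J + 1], field.f_a[: J + 1])
    return ActivityProfile(r_grid=r, a=np.asarray(a), regime=classify_regime(a, tol))
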