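"""Dimensional tissue and factor parameters and their nondimensional groups.

The model works with a spherical tumor of radius ``R`` embedded in host
tissue.  Each tissue carries vascular/interstitial transport properties
(:class:`TissueProperties`) and, per angiogenic-factor family, kinetic
constants (:class:`FactorKinetics`).  All solvers operate on the
nondimensional groups derived here:

* ``alpha = R * sqrt(Lp * (S/V) / K)`` — ratio of transvascular fluid
  exchange to interstitial conduction; sets how steeply interstitial fluid
  pressure (IFP) falls at the tumor rim.
* ``p_e = p_v - sigma * (pi_v - pi_i)`` — effective pressure the vasculature
  imposes on the interstitium (Starling balance); the pressure scale.
* ``k_tilde = k R^2 / D``, ``g_tilde = g R^2 / (D f_s)``,
  ``K_tilde = K p_e / D`` — deactivation, production and convection strength
  per factor family and tissue, with ``f_s = g_host / k_host`` the host
  steady-state concentration used to scale concentrations.

A single *global* pressure scale is used throughout: ``p_e`` of the tumor
tissue (20 mmHg by default) nondimensionalizes the pressure everywhere,
including host-tissue ``K_tilde``.  Host effective pressure is still
reported as a per-tissue property.

Units: lengths mm, time s, pressure mmHg, concentration µg/mm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TissueProperties",
    "FactorKinetics",
    "Geometry",
    "NondimGroups",
    "effective_pressure",
    "alpha",
    "alpha_value",
    "lp_for_alpha",
    "nondimensionalize",
]


def _require_positive(name: str, value: float) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class TissueProperties:
    """Vascular and interstitial transport properties of one tissue.

    Parameters
    ----------
    K : float
        Interstitial hydraulic conductivity (mm²/s/mmHg).
    Lp : float
        Hydraulic permeability of the microvascular wall (mm/s/mmHg).
    SV : float
        Vessel surface area per unit tissue volume S/V (mm²/mm³).
    pv : float
        Vascular (microvascular) pressure (mmHg).
    sigma : float
        Average osmotic reflection coefficient for plasma proteins, in [0, 1].
    pi_v, pi_i : float
        Plasma and interstitial osmotic pressures (mmHg).
    """

    K: float
    Lp: float
    SV: float
    pv: float
    sigma: float
    pi_v: float
    pi_i: float

    def __post_init__(self) -> None:
        for name in ("K", "Lp", "SV", "pv", "pi_v", "pi_i"):
            _require_positive(name, getattr(self, name))
        if not (0.0 <= self.sigma <= 1.0):
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma!r}")

    @property
    def effective_pressure(self) -> float:
        """Starling effective pressure p_e = p_v − σ(π_v − π_i), in mmHg."""
        return self.pv - self.sigma * (self.pi_v - self.pi_i)

    def alpha(self, R: float) -> float:
        """Dimensionless pressure parameter α = R·sqrt(Lp·(S/V)/K)."""
        _require_positive("R", R)
        return alpha_value(R, self.Lp, self.SV, self.K)

    def with_(self, **changes: float) -> "TissueProperties":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class FactorKinetics:
    """Transport/kinetic constants of one angiogenic-factor family in one tissue.

    D: diffusion coefficient (mm²/s); k: first-order deactivation rate (1/s);
    g: production rate (µg/mm³/s).
    """

    D: float
    k: float
    g: float

    def __post_init__(self) -> None:
        for name in ("D", "k", "g"):
            _require_positive(name, getattr(self, name))

    def with_(self, **changes: float) -> "FactorKinetics":
        return replace(self, **changes)


@dataclass(frozen=True)
class Geometry:
    """Radial computational domain.

    ``R`` is the tumor radius in mm; the nondimensional coordinate is
    r̃ = r/R, running from 0 to ``r_max`` (so the physical domain extends to
    ``r_max * R``).  The grid is uniform and must place a node exactly on the
    tumor boundary r̃ = 1.
    """

    R: float = 4.0
    r_max: float = 5.0
    n_grid: int = 2001

    def __post_init__(self) -> None:
        _require_positive("R", self.R)
        if self.r_max < 3:
            raise ValueError(f"r_max must be >= 3 (domain must enclose the tumor comfortably), got {self.r_max!r}")
        if self.n_grid < 101:
            raise ValueError(f"n_grid must be >= 101, got {self.n_grid!r}")
        # A node must land exactly on the interface r̃ = 1.
        h = self.r_max / (self.n_grid - 1)
        if abs(round(1.0 / h) * h - 1.0) > 1e-12:
            raise ValueError(
                f"grid (r_max={self.r_max}, n_grid={self.n_grid}) places no node on r̃=1; "
                "choose n_grid such that (n_grid-1)/r_max is an integer"
            )

    @property
    def h(self) -> float:
        """Grid spacing in r̃."""
        return self.r_max / (self.n_grid - 1)

    @property
    def interface_index(self) -> int:
        """Index of the node sitting on the tumor boundary r̃ = 1."""
        return round(1.0 / self.h)

    def r_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.n_grid)

    def refined(self, factor: int = 2) -> "Geometry":
        """Geometry with the grid spacing divided by ``factor``."""
        return Geometry(self.R, self.r_max, (self.n_grid - 1) * factor + 1)


@dataclass(frozen=True)
class NondimGroups:
    """Nondimensional groups for one factor family in one tissue.

    k_tilde = k R²/D, g_tilde = g R²/(D f_s), K_tilde = K p_e/D, together
    with the pressure parameter alpha of the tissue, the global pressure
    scale p_e (mmHg), the host steady-state concentration f_s (µg/mm³) and
    the tissue diffusion coefficient D (mm²/s, needed for interface flux
    matching between tissues).
    """

    k_tilde: float
    g_tilde: float
    K_tilde: float
    alpha: float
    pe: float
    f_s: float
    D: float

    def __post_init__(self) -> None:
        for name in ("k_tilde", "g_tilde", "K_tilde", "alpha"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be nonnegative and finite, got {v!r}")

    def with_(self, **changes: float) -> "NondimGroups":
        return replace(self, **changes)


def effective_pressure(t: TissueProperties) -> float:
    """Effective pressure p_e = p_v − σ(π_v − π_i) of a tissue, in mmHg."""
    return t.effective_pressure


def alpha_value(R: float, Lp: float, SV: float, K: float) -> float:
    """α = R·sqrt(Lp·(S/V)/K) from raw values; accepts Lp = 0 (avascular)."""
    if Lp < 0 or SV < 0:
        raise ValueError("Lp and S/V must be nonnegative")
    _require_positive("K", K)
    _require_positive("R", R)
    return R * math.sqrt(Lp * SV / K)


def alpha(t: TissueProperties, R: float) -> float:
    """Dimensionless pressure parameter of a tissue for tumor radius R (mm)."""
    return t.alpha(R)


def lp_for_alpha(alpha_target: float, R: float, SV: float, K: float) -> float:
    """Invert α = R·sqrt(Lp·(S/V)/K) for the vascular permeability Lp."""
    if alpha_target < 0:
        raise ValueError("alpha must be nonnegative")
    _require_positive("R", R)
    _require_positive("SV", SV)
    _require_positive("K", K)
    return alpha_target**2 * K / (R**2 * SV)


def nondimensionalize(
    tumor: FactorKinetics,
    host: FactorKinetics,
    geom: Geometry,
    K: float,
    pe: float,
    alpha_tumor: float = 0.0,
    alpha_host: float = 0.0,
) -> dict[str, NondimGroups]:
    """Nondimensional groups for one factor family in tumor and host tissue.

    The concentration scale f_s = g_host / k_host (host steady state) is
    shared by both tissues, so host g̃ equals host k̃ by construction.  The
    pressure scale ``pe`` is global (see module docstring).

    Returns a dict with keys ``"tumor"`` and ``"host"``.
    """
    f_s = host.g / host.k
    if not (f_s > 0) or not math.isfinite(f_s):
        raise ValueError(f"host steady-state concentration f_s = g/k must be positive, got {f_s!r}")
    _require_positive("K", K)
    _require_positive("pe", pe)
    R2 = geom.R**2
    out = {}
    for name, kin, a in (("tumor", tumor, alpha_tumor), ("host", host, alpha_host)):
        out[name] = NondimGroups(
            k_tilde=kin.k * R2 / kin.D,
            g_tilde=kin.g * R2 / (kin.D * f_s),
            K_tilde=K * pe / kin.D,
            alpha=a,
            pe=pe,
            f_s=f_s,
            D=kin.D,
        )
    return out
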