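"""Steady convection–diffusion–reaction transport of angiogenic factors.

Each factor family obeys, per region (tumor r̃ < 1, host r̃ > 1), the
nondimensional steady balance

    (1/r̃²) d/dr̃ [ r̃² ( df̃/dr̃ + K̃ (dp̃/dr̃) f̃ ) ] − k̃ f̃ + g̃ = 0,

i.e. diffusion plus convection by the interstitial fluid (velocity
ũ = −dp̃/dr̃), first-order deactivation and constant production.
Concentrations are scaled by the host steady state f_s = g_h/k_h, so
f̃ → 1 far from the tumor.  At the tumor boundary the concentration and the
dimensional flux −D ∂f/∂r + u·f are continuous; since D differs between
tissues the flux-matching carries the ratio D_t/D_h explicitly.

The discretization is a conservative finite-volume scheme: fluxes are
evaluated at cell faces with centered (second-order) differences and the
region's D-weighting, so the sum over cells telescopes and the discrete
production − degradation − outflux balance closes to solver precision.
High cell-Péclet situations trigger automatic grid refinement rather than
upwinding, preserving second-order accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .ifp import PressureField
from .params import Geometry, NondimGroups

__all__ = [
    "FactorField",
    "AGFOperator",
    "solve_agf",
    "solve_agf_no_convection_analytic",
]

logger = logging.getLogger("angiofield.agf")


@dataclass(frozen=True)
class FactorField:
    """Nondimensional factor concentrations f̃_p, f̃_a on a radial grid.

    ``balance`` holds, per factor, the relative defect of the discrete
    production − degradation − outer-flux budget (diagnostic; ~1e-14 for a
    healthy solve).
    """

    r_grid: np.ndarray
    f_p: np.ndarray
    f_a: np.ndarray
    balance: dict | None = None

    @property
    def interface_index(self) -> int:
        return int(np.argmin(np.abs(self.r_grid - 1.0)))


class AGFOperator:
    """Assembled transport operator for one factor family on a fixed grid.

    The matrix depends on k̃, K̃, the pressure gradient and the geometry but
    *not* on the production rates g̃, which only enter the right-hand side.
    The LU factorization is therefore reused across production values — the
    production-plane sweeps exploit this.
    """

    def __init__(
        self,
        tumor: NondimGroups,
        host: NondimGroups,
        pressure: PressureField,
        geom: Geometry,
        far_field: float = 1.0,
    ):
        r = geom.r_grid()
        if pressure.r_grid.shape != r.shape or not np.allclose(pressure.r_grid, r):
            pressure = pressure.on_grid(geom)
        n, h, J = geom.n_grid, geom.h, geom.interface_index
        self.geom = geom
        self.tumor = tumor
        self.host = host
        self.far_field = far_field

        r_face = r[:-1] + 0.5 * h  # faces i+1/2, i = 0..n-2
        s_face = np.diff(pressure.p_tilde) / h  # dp̃/dr̃ at faces, second order
        in_tumor = r_face < 1.0
        D_face = np.where(in_tumor, tumor.D, host.D)
        Kt_face = np.where(in_tumor, tumor.K_tilde, host.K_tilde)
        self.peclet = float(np.max(np.abs(Kt_face * s_face)) * h)

        # Face-flux coefficients: G_{i+1/2} = a_lo*f_i + a_hi*f_{i+1}
        conv = 0.5 * Kt_face * s_face
        a_lo = D_face * r_face**2 * (-1.0 / h + conv)
        a_hi = D_face * r_face**2 * (1.0 / h + conv)

        # Cell volumes (r̃²-weighted), split at the interface node.
        rf3 = r_face**3
        V = np.empty(n)
        V[0] = rf3[0] / 3.0
        V[1:-1] = np.diff(rf3) / 3.0
        V[-1] = (geom.r_max**3 - rf3[-1]) / 3.0
        V_minus = (1.0 - rf3[J - 1]) / 3.0  # tumor half of the interface cell
        V_plus = (rf3[J] - 1.0) / 3.0

        Dk = np.where(np.arange(n) < J, tumor.D * tumor.k_tilde, host.D * host.k_tilde)

        rows, cols, vals = [], [], []

        def add(i, j, v):
            rows.append(i)
            cols.append(j)
            vals.append(v)

        # cell 0 (origin half-cell): G_{1/2} − D k̃ V f_0 = −D g̃ V
        add(0, 0, a_lo[0] - Dk[0] * V[0])
        add(0, 1, a_hi[0])
        for i in range(1, n - 1):
            add(i, i - 1, -a_lo[i - 1])
            add(i, i, a_lo[i] - a_hi[i - 1] - (Dk[i] * V[i] if i != J else tumor.D * tumor.k_tilde * V_minus + host.D * host.k_tilde * V_plus))
            add(i, i + 1, a_hi[i])
        add(n - 1, n - 1, 1.0)  # Dirichlet far field

        A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        try:
            self._lu = splu(A)
        except RuntimeError as exc:  # pragma: no cover - singular configuration
            raise RuntimeError(f"singular factor-transport system: {exc}") from exc
        self._V = V
        self._V_minus, self._V_plus = V_minus, V_plus
        self._J = J
        self._a_lo, self._a_hi = a_lo, a_hi

    def _rhs(self, g_tumor: float, g_host: float) -> np.ndarray:
        n = self.geom.n_grid
        J = self._J
        rhs = np.empty(n)
        Dg = np.where(np.arange(n) < J, self.tumor.D * g_tumor, self.host.D * g_host)
        rhs[:] = -Dg * self._V
        rhs[J] = -(self.tumor.D * g_tumor * self._V_minus + self.host.D * g_host * self._V_plus)
        rhs[-1] = self.far_field
        return rhs

    def solve(self, g_tilde_tumor: float | None = None, g_tilde_host: float | None = None) -> np.ndarray:
        """Concentration profile, optionally overriding the production rates."""
        g_t = self.tumor.g_tilde if g_tilde_tumor is None else g_tilde_tumor
        g_h = self.host.g_tilde if g_tilde_host is None else g_tilde_host
        f = self._lu.solve(self._rhs(g_t, g_h))
        if not np.all(np.isfinite(f)):
            raise RuntimeError("factor-transport solve produced non-finite values (singular system?)")
        return f

    def balance_residual(
        self, f: np.ndarray, g_tilde_tumor: float | None = None, g_tilde_host: float | None = None
    ) -> float:
        """Relative defect of production − degradation − outflux.

        The outward flux through the last interior face is compared with the
        net r̃²-weighted source integrated over all cells inside it; the
        conservative scheme closes this budget to solver precision.
        """
        g_t = self.tumor.g_tilde if g_tilde_tumor is None else g_tilde_tumor
        g_h = self.host.g_tilde if g_tilde_host is None else g_tilde_host
        J = self._J
        n = self.geom.n_grid
        out_flux = -(self._a_lo[-1] * f[-2] + self._a_hi[-1] * f[-1])
        production = 0.0
        degradation = 0.0
        for i in range(n - 1):
            if i < J:
                production += self.tumor.D * g_t * self._V[i]
                degradation += self.tumor.D * self.tumor.k_tilde * f[i] * self._V[i]
            elif i > J:
                production += self.host.D * g_h * self._V[i]
                degradation += self.host.D * self.host.k_tilde * f[i] * self._V[i]
            else:
                production += self.tumor.D * g_t * self._V_minus + self.host.D * g_h * self._V_plus
                degradation += (
                    self.tumor.D * self.tumor.k_tilde * f[i] * self._V_minus
                    + self.host.D * self.host.k_tilde * f[i] * self._V_plus
                )
        scale = max(abs(production), abs(degradation), abs(out_flux), 1e-300)
        return abs(production - degradation - out_flux) / scale


def solve_agf(
    groups: Mapping[str, Mapping[str, NondimGroups]],
    pressure: PressureField,
    geom: Geometry,
    far_field: float = 1.0,
    max_refinements: int = 3,
) -> FactorField:
    """Solve factor transport for both families on the shared grid.

    ``groups`` maps factor name (``"pro"``, ``"anti"``) to per-tissue
    :class:`~angiofield.params.NondimGroups` (keys ``"tumor"``, ``"host"``).
    If any face's cell Péclet number K̃·|dp̃/dr̃|·h exceeds 2 the grid is
    refined (spacing halved, pressure re-evaluated) up to ``max_refinements``
    times, preserving the centered second-order scheme.
    """
    for _ in range(max_refinements + 1):
        ops = {
            fac: AGFOperator(g["tumor"], g["host"], pressure, geom, far_field)
            for fac, g in groups.items()
        }
        pe = max(op.peclet for op in ops.values())
        if pe <= 2.0:
            break
        warnings.warn(
            f"cell Péclet number {pe:.2f} > 2; refining grid from n={geom.n_grid}",
            stacklevel=2,
        )
        geom = geom.refined(2)
    solutions = {fac: op.solve() for fac, op in ops.items()}
    balance = {fac: ops[fac].balance_residual(f) for fac, f in solutions.items()}
    logger.debug(
        "factor transport solved: n_grid=%d, cell Péclet=%.3g, balance residuals=%s",
        geom.n_grid,
        pe,
        {k: float(v) for k, v in balance.items()},
    )
    return FactorField(
        r_grid=geom.r_grid(),
        f_p=solutions["pro"],
        f_a=solutions["anti"],
        balance=balance,
    )


def solve_agf_no_convection_analytic(
    groups: Mapping[str, Mapping[str, NondimGroups]],
    geom: Geometry,
) -> FactorField:
    """Closed-form diffusion–reaction solution (no convection, K̃ = 0).

    Interior: f̃ = g̃_t/k̃_t + A·sinh(√k̃_t·r̃)/r̃ (regular at the origin);
    exterior: f̃ = 1 + C·exp(−√k̃_h(r̃−1))/r̃ (host steady state far away).
    A and C follow from continuity of concentration and of the dimensional
    diffusive flux −D ∂f/∂r at r̃ = 1 — a 2×2 linear system in which the
    diffusivity ratio D_t/D_h enters explicitly.
    """
    r = geom.r_grid()
    out = {}
    for fac, g in groups.items():
        t, hst = g["tumor"], g["host"]
        if t.k_tilde <= 0 or hst.k_tilde <= 0:
            raise ValueError("closed form requires strictly positive deactivation rates")
        P = t.g_tilde / t.k_tilde
        s_t, s_h = np.sqrt(t.k_tilde), np.sqrt(hst.k_tilde)
        d_ratio = t.D / hst.D
        denom = np.sinh(s_t) + d_ratio * (s_t * np.cosh(s_t) - np.sinh(s_t)) / (1.0 + s_h)
        if denom == 0 or not np.isfinite(denom):
            raise RuntimeError("singular interface matching in closed-form factor solution")
        A = (1.0 - P) / denom
        C = P - 1.0 + A * np.sinh(s_t)

        f = np.empty_like(r)
        inside = r <= 1.0
        ri = r[inside]
        with np.errstate(invalid="ignore", divide="ignore"):
            dev = np.where(ri > 0, A * np.sinh(s_t * ri) / np.where(ri > 0, ri, 1.0), A * s_t)
        f[inside] = P + dev
        ro = r[~inside]
        f[~inside] = 1.0 + C * np.exp(-s_h * (ro - 1.0)) / ro
        out[fac] = f
    return FactorField(r_grid=r, f_p=out["pro"], f_a=out["anti"], balance=None)
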