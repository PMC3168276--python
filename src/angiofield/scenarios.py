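"""End-to-end scenario runs and parameter studies.

A scenario is the default configuration plus a set of overrides addressed by
dotted parameter paths (``tumor.Lp``, ``global.pe``, ``global.K``,
``tumor.g_p``, ``tumor.g_p_tilde`` …).  Derived quantities — α, the
convection parameters K̃ — are always recomputed from the resolved
dimensional values, never set directly, so the physical couplings are
preserved automatically: changing K moves both α and K̃, changing Lp moves
only α, changing p_e moves only K̃.

``sweep_production_plane`` maps the regime label over the
(g̃_p^t, g̃_a^t) tumor-production plane at fixed pressure field (pressure is
independent of factor kinetics in this model), reusing one LU factorization
per factor family across the whole sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np

from .activity import ActivityProfile, activity, activity_profile, classify_regime
from .agf import AGFOperator, FactorField, solve_agf
from .config import ModelConfig, load_config
from .ifp import PressureField, solve_ifp_analytic
from .params import Geometry, lp_for_alpha

logger = logging.getLogger("angiofield.scenarios")

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "RegimeMap",
    "run_scenario",
    "sweep_production_plane",
    "cytotoxic_table_presets",
    "therapy_presets",
]

# Shorthand override paths for factor kinetics: tumor.g_p -> factors.pro.tumor.g
_FACTOR_SHORTHAND = {
    f"{field}_{suffix}": ("pro" if suffix == "p" else "anti", field)
    for field in ("D", "k", "g")
    for suffix in ("p", "a")
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Named parameter study: defaults plus overrides.

    Override paths:

    * ``<tissue>.<prop>`` — tissue property (``tumor.Lp``, ``host.SV`` …)
    * ``<tissue>.<kin>_<p|a>`` — dimensional factor kinetics
      (``tumor.g_p``, ``tumor.k_a`` …)
    * ``<tissue>.g_<p|a>_tilde`` — tumor production set nondimensionally
      (for sweeps quoted in g̃ units)
    * ``global.K`` — hydraulic conductivity of every tissue
    * ``global.pe`` — explicit pressure scale (mmHg)
    * ``geometry.<R|r_max|n_grid>``
    * ``tumor_tissue`` — which column plays the tumor (``"normalized"``
      for a vascular-normalized tumor)
    """

    name: str
    overrides: Mapping = dc_field(default_factory=dict)
    description: str = ""

    def resolve(self, base: ModelConfig | None = None) -> tuple[ModelConfig, dict, str]:
        """Apply the overrides; returns (config, g̃ overrides, tumor tissue)."""
        cfg = base if base is not None else load_config()
        raw = cfg.to_dict()
        raw.pop("pe_override", None)
        pe_override = cfg.pe_override
        g_tilde: dict[str, float] = {}
        tumor_tissue = "tumor"

        for path, value in self.overrides.items():
            parts = path.split(".")
            if path == "tumor_tissue":
                if value not in ("tumor", "normalized"):
                    raise ValueError(f"scenario {self.name!r}: tumor_tissue must be 'tumor' or 'normalized'")
                tumor_tissue = value
            elif path == "global.pe":
                pe_override = float(value)
            elif path == "global.K":
                for t in raw["tissues"]:
                    raw["tissues"][t]["K"] = float(value)
            elif parts[0] == "geometry" and len(parts) == 2:
                raw["geometry"][parts[1]] = value
            elif parts[0] == "factors" and len(parts) == 4:
                raw["factors"][parts[1]][parts[2]][parts[3]] = float(value)
            elif len(parts) == 2 and parts[1] in ("g_p_tilde", "g_a_tilde"):
                if parts[0] != "tumor":
                    raise ValueError(
                        f"scenario {self.name!r}: nondimensional production overrides apply to the tumor only"
                    )
                g_tilde["pro" if parts[1] == "g_p_tilde" else "anti"] = float(value)
            elif len(parts) == 2 and parts[1] in _FACTOR_SHORTHAND:
                fac, kin_field = _FACTOR_SHORTHAND[parts[1]]
                raw["factors"][fac][parts[0]][kin_field] = float(value)
            elif len(parts) == 2 and parts[0] in raw["tissues"]:
                raw["tissues"][parts[0]][parts[1]] = float(value)
            else:
                raise ValueError(f"scenario {self.name!r}: unknown override path {path!r}")

        if pe_override is not None:
            raw["pe_override"] = pe_override
        from .config import _resolve  # late import to avoid cycle at module load

        try:
            resolved = _resolve(raw)
        except ValueError as exc:
            raise ValueError(f"scenario {self.name!r}: {exc}") from exc
        return resolved, g_tilde, tumor_tissue


@dataclass(frozen=True)
class ScenarioResult:
    """Solved pipeline output for one scenario."""

    spec: ScenarioSpec
    config: ModelConfig
    pressure: PressureField
    factors: FactorField
    activity: ActivityProfile
    groups: dict = dc_field(default_factory=dict)  # resolved NondimGroups per factor/tissue

    @property
    def regime(self) -> str:
        return self.activity.regime

    def record(self) -> dict:
        """Machine-parsable run summary (dimensional + nondimensional)."""
        cfg = self.config
        groups = {
            fac: {t: vars(g).copy() for t, g in block.items()} for fac, block in self.groups.items()
        }
        return {
            "scenario": self.spec.name,
            "parameters": cfg.to_dict(),
            "nondimensional": groups,
            "grid": {"r_max": cfg.geometry.r_max, "n_grid": cfg.geometry.n_grid},
            "alpha_t": self.pressure.alpha_t,
            "alpha_h": self.pressure.alpha_h,
            "pe": cfg.pe,
            "regime": self.regime,
            "summary": {
                "p_center": float(self.pressure.p_tilde[0]),
                "u_peak": float(np.max(self.pressure.u_tilde)),
                "a_peak": self.activity.peak,
                "a_peak_location": self.activity.peak_location,
                "stimulated_fraction": self.activity.stimulated_fraction(),
            },
        }


def _patched_groups(cfg: ModelConfig, g_tilde: Mapping[str, float], tumor_tissue: str) -> dict:
    groups = {fac: cfg.groups(fac, tumor_tissue) for fac in ("pro", "anti")}
    for fac, value in g_tilde.items():
        groups[fac]["tumor"] = groups[fac]["tumor"].with_(g_tilde=value)
    return groups


def run_scenario(spec: ScenarioSpec, base: ModelConfig | None = None) -> ScenarioResult:
    """Full pipeline: resolve parameters → IFP → factor transport → regime."""
    cfg, g_tilde, tumor_tissue = spec.resolve(base)
    geom = cfg.geometry
    try:
        alpha_t = cfg.alpha(tumor_tissue)
        alpha_h = cfg.alpha("host")
        k_ratio = cfg.tissues["host"].K / cfg.tissues[tumor_tissue].K
        pressure = solve_ifp_analytic(alpha_t, alpha_h, geom, k_ratio)
        groups = _patched_groups(cfg, g_tilde, tumor_tissue)
        factors = solve_agf(groups, pressure, geom)
        act = activity_profile(factors)
    except Exception as exc:
        raise RuntimeError(f"scenario {spec.name!r} failed: {exc}") from exc
    logger.info(
        "scenario %s: alpha_t=%.4g alpha_h=%.4g pe=%.4g -> %s",
        spec.name, alpha_t, alpha_h, cfg.pe, act.regime,
    )
    return ScenarioResult(
        spec=spec, config=cfg, pressure=pressure, factors=factors, activity=act, groups=groups
    )


@dataclass(frozen=True)
class RegimeMap:
    """Regime labels over the tumor-production plane (g̃_p^t × g̃_a^t).

    ``labels[i, j]`` is the regime at ``(g_p_axis[i], g_a_axis[j])``;
    ``boundaries`` maps a sorted label pair to the midpoints between
    differently-labeled neighboring cells (qualitative polylines, no subgrid
    refinement).
    """

    g_p_axis: np.ndarray
    g_a_axis: np.ndarray
    labels: np.ndarray  # dtype=object (str), shape (len(g_p_axis), len(g_a_axis))
    boundaries: dict
    alpha_t: float
    alpha_h: float

    def label_at(self, g_p: float, g_a: float) -> str:
        """Label of the grid cell nearest to the given production pair."""
        i = int(np.argmin(np.abs(self.g_p_axis - g_p)))
        j = int(np.argmin(np.abs(self.g_a_axis - g_a)))
        return str(self.labels[i, j])

    def band_area(self, regime: str) -> float:
        """Area of the region carrying ``regime``, in g̃_p·g̃_a units."""
        dp = self.g_p_axis[1] - self.g_p_axis[0] if len(self.g_p_axis) > 1 else 1.0
        da = self.g_a_axis[1] - self.g_a_axis[0] if len(self.g_a_axis) > 1 else 1.0
        return float(np.sum(self.labels == regime) * dp * da)


def _extract_boundaries(g_p_axis, g_a_axis, labels) -> dict:
    boundaries: dict[tuple, list] = {}
    ni, nj = labels.shape
    for i in range(ni):
        for j in range(nj):
            for di, dj in ((1, 0), (0, 1)):
                ii, jj = i + di, j + dj
                if ii >= ni or jj >= nj:
                    continue
                a, b = labels[i, j], labels[ii, jj]
                if a != b:
                    key = tuple(sorted((a, b)))
                    mid = (
                        0.5 * (g_p_axis[i] + g_p_axis[ii]),
                        0.5 * (g_a_axis[j] + g_a_axis[jj]),
                    )
                    boundaries.setdefault(key, []).append(mid)
    return {k: np.array(sorted(v)) for k, v in boundaries.items()}


def sweep_production_plane(
    alpha_t: float,
    g_p_range: tuple[float, float] = (100.0, 600.0),
    g_a_range: tuple[float, float] = (100.0, 500.0),
    n_per_axis: int = 41,
    base: ModelConfig | None = None,
    alpha_h: float | None = None,
) -> RegimeMap:
    """Regime map over tumor production rates at a fixed pressure field.

    The pressure profile depends only on (α_t, α_h), so it — and the factor
    transport operators, whose matrices are independent of production — are
    built once; each factor family is then solved for every axis value by
    LU back-substitution and the 2-D grid of labels assembled from the
    pairwise activity profiles.
    """
    cfg = base if base is not None else load_config()
    geom = cfg.geometry
    if alpha_h is None:
        alpha_h = cfg.alpha("host")
    pressure = solve_ifp_analytic(alpha_t, alpha_h, geom)
    J = geom.interface_index

    g_p_axis = np.linspace(*g_p_range, n_per_axis)
    g_a_axis = np.linspace(*g_a_range, n_per_axis)

    solutions = {}
    for fac, axis in (("pro", g_p_axis), ("anti", g_a_axis)):
        g = cfg.groups(fac)
        op = AGFOperator(g["tumor"], g["host"], pressure, geom)
        solutions[fac] = np.stack([op.solve(g_tilde_tumor=v)[: J + 1] for v in axis])

    labels = np.empty((n_per_axis, n_per_axis), dtype=object)
    for i in range(n_per_axis):
        f_p = solutions["pro"][i]
        for j in range(n_per_axis):
            a = activity(f_p, solutions["anti"][j])
            labels[i, j] = classify_regime(a)

    return RegimeMap(
        g_p_axis=g_p_axis,
        g_a_axis=g_a_axis,
        labels=labels,
        boundaries=_extract_boundaries(g_p_axis, g_a_axis, labels),
        alpha_t=alpha_t,
        alpha_h=alpha_h,
    )


def cytotoxic_table_presets(base: ModelConfig | None = None) -> list[ScenarioSpec]:
    """The six cytotoxic-therapy scenarios: α_t ∈ {2, 6, 14} × g̃_p^t ∈ {349, 279}.

    α_t is dialed through the vascular permeability Lp alone (S/V and R stay
    at their tumor-column values); the cytotoxic column lowers only the
    nondimensional proangiogenic production (349 → 279), leaving the
    antiangiogenic production at 280.
    """
    cfg = base if base is not None else load_config()
    t = cfg.tissues["tumor"]
    R = cfg.geometry.R
    specs = []
    for alpha_t in (2.0, 6.0, 14.0):
        lp = lp_for_alpha(alpha_t, R, t.SV, t.K)
        for g_p, therapy in ((349.0, "no_treatment"), (279.0, "cytotoxic")):
            specs.append(
                ScenarioSpec(
                    name=f"{therapy}_alpha{alpha_t:g}",
                    overrides={
                        "tumor.Lp": lp,
                        "tumor.g_p_tilde": g_p,
                        "tumor.g_a_tilde": 280.0,
                    },
                    description=(
                        f"alpha_t={alpha_t:g} via Lp={lp:.3e}; "
                        f"g_p_tilde={g_p:g} ({therapy.replace('_', ' ')}), g_a_tilde=280"
                    ),
                )
            )
    return specs


def therapy_presets(base: ModelConfig | None = None) -> list[ScenarioSpec]:
    """Therapy-like parameter changes: the six cytotoxic scenarios plus
    vascular-normalization, proangiogenic-deactivation and ECM-degradation
    presets.

    The two normalization presets record both readings of the α_t = 6 state:
    lowering Lp to 3.7e-6 with the vessel density also reduced to S/V = 15.2,
    or adopting the full normalized tissue column.
    """
    specs = cytotoxic_table_presets(base)
    specs.append(
        ScenarioSpec(
            name="normalization_lp_sv",
            overrides={"tumor.Lp": 3.7e-6, "tumor.SV": 15.2},
            description="vascular normalization: Lp 1.86e-5 -> 3.7e-6 and S/V 16.5 -> 15.2 (alpha_t = 6)",
        )
    )
    specs.append(
        ScenarioSpec(
            name="normalization_column",
            overrides={"tumor_tissue": "normalized"},
            description="vascular normalization: full normalized tissue column plays the tumor",
        )
    )
    specs.append(
        ScenarioSpec(
            name="antiangiogenic_deactivation",
            overrides={"tumor.k_p": 1.99e-4 * 1.25},
            description="antiangiogenic agent raising proangiogenic deactivation by 25%",
        )
    )
    specs.append(
        ScenarioSpec(
            name="ecm_degradation",
            overrides={"global.K": 5.0e-5, "global.pe": 10.9},
            description="ECM-degrading enzymes double K (lower alpha, stronger convection), pe = 10.9 mmHg",
        )
    )
    return specs
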