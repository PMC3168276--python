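"""Configuration loading, validation and the resolved parameter set.

A configuration has a ``geometry`` block, three tissue blocks
(host / tumor / normalized) and, per factor family (pro / anti), kinetic
blocks for each tissue.  The shipped defaults describe a 4 mm tumor with
literature transport parameters; ``load_config`` overlays a user YAML/JSON
file (or an in-memory mapping) on those defaults and validates everything at
construction time — solvers never re-validate.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .params import FactorKinetics, Geometry, NondimGroups, TissueProperties, nondimensionalize

__all__ = ["ModelConfig", "load_config", "default_config_dict"]

TISSUES = ("host", "tumor", "normalized")
FACTORS = ("pro", "anti")

_TISSUE_FIELDS = {"K", "Lp", "SV", "pv", "sigma", "pi_v", "pi_i"}
_KINETIC_FIELDS = {"D", "k", "g"}
_GEOMETRY_FIELDS = {"R", "r_max", "n_grid"}


def default_config_dict() -> dict:
    """The shipped default parameter set as a plain nested dict."""
    text = resources.files("angiofield.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _check_keys(block: Mapping, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


@dataclass(frozen=True)
class ModelConfig:
    """Fully resolved, validated parameter set.

    Immutable; scenario machinery derives modified copies rather than
    mutating.  ``pe`` is the single global pressure scale (the tumor-tissue
    effective pressure unless explicitly overridden).
    """

    geometry: Geometry
    tissues: dict  # tissue name -> TissueProperties
    factors: dict  # factor name -> {tissue name -> FactorKinetics}
    pe_override: float | None = None

    @property
    def pe(self) -> float:
        """Global pressure scale (mmHg): tumor effective pressure by default."""
        if self.pe_override is not None:
            return self.pe_override
        return self.tissues["tumor"].effective_pressure

    @property
    def K(self) -> float:
        """Interstitial hydraulic conductivity used by the solvers (tumor value)."""
        return self.tissues["tumor"].K

    def alpha(self, tissue: str) -> float:
        return self.tissues[tissue].alpha(self.geometry.R)

    def groups(self, factor: str, tumor_tissue: str = "tumor") -> dict[str, NondimGroups]:
        """Nondimensional groups for one factor family.

        ``tumor_tissue`` selects which column plays the tumor role (e.g.
        ``"normalized"`` for a vascular-normalized tumor).
        """
        return nondimensionalize(
            self.factors[factor][tumor_tissue],
            self.factors[factor]["host"],
            self.geometry,
            K=self.K,
            pe=self.pe,
            alpha_tumor=self.alpha(tumor_tissue),
            alpha_host=self.alpha("host"),
        )

    def to_dict(self) -> dict:
        """Plain nested dict of all dimensional parameters."""
        out: dict[str, Any] = {
            "geometry": {"R": self.geometry.R, "r_max": self.geometry.r_max, "n_grid": self.geometry.n_grid},
            "tissues": {
                name: {f: getattr(t, f) for f in sorted(_TISSUE_FIELDS)} for name, t in self.tissues.items()
            },
            "factors": {
                fac: {name: {f: getattr(k, f) for f in sorted(_KINETIC_FIELDS)} for name, k in block.items()}
                for fac, block in self.factors.items()
            },
        }
        if self.pe_override is not None:
            out["pe_override"] = self.pe_override
        return out


def _resolve(raw: Mapping) -> ModelConfig:
    _check_keys(raw, {"geometry", "tissues", "factors", "pe_override"}, "top level")
    for section in ("geometry", "tissues", "factors"):
        if section not in raw:
            raise ValueError(f"missing required section '{section}'")

    geo = raw["geometry"]
    _check_keys(geo, _GEOMETRY_FIELDS, "geometry")
    geometry = Geometry(R=float(geo["R"]), r_max=float(geo["r_max"]), n_grid=int(geo["n_grid"]))

    tissues = {}
    for name in TISSUES:
        if name not in raw["tissues"]:
            raise ValueError(f"missing tissue block '{name}'")
        block = raw["tissues"][name]
        _check_keys(block, _TISSUE_FIELDS, f"tissues.{name}")
        try:
            tissues[name] = TissueProperties(**{k: float(v) for k, v in block.items()})
        except ValueError as exc:
            raise ValueError(f"tissues.{name}: {exc}") from exc
    _check_keys(raw["tissues"], set(TISSUES), "tissues")

    factors: dict[str, dict[str, FactorKinetics]] = {}
    _check_keys(raw["factors"], set(FACTORS), "factors")
    for fac in FACTORS:
        if fac not in raw["factors"]:
            raise ValueError(f"missing factor block '{fac}'")
        factors[fac] = {}
        _check_keys(raw["factors"][fac], set(TISSUES), f"factors.{fac}")
        for name in TISSUES:
            if name not in raw["factors"][fac]:
                raise ValueError(f"missing kinetics block 'factors.{fac}.{name}'")
            block = raw["factors"][fac][name]
            _check_keys(block, _KINETIC_FIELDS, f"factors.{fac}.{name}")
            try:
                factors[fac][name] = FactorKinetics(**{k: float(v) for k, v in block.items()})
            except ValueError as exc:
                raise ValueError(f"factors.{fac}.{name}: {exc}") from exc

    pe_override = raw.get("pe_override")
    return ModelConfig(
        geometry=geometry,
        tissues=tissues,
        factors=factors,
        pe_override=None if pe_override is None else float(pe_override),
    )


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> ModelConfig:
    """Load the default configuration, optionally overlaying a file and/or dict.

    Parameters
    ----------
    path : str or Path, optional
        YAML (or JSON) file whose entries override the shipped defaults.
        Partial files are fine: only the provided leaves are replaced.
    overrides : mapping, optional
        In-memory nested mapping applied after the file.

    Raises
    ------
    ValueError
        On unknown keys, missing tissue/factor blocks or invalid values,
        with a message naming the offending entry.
    """
    raw = default_config_dict()
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        text = p.read_text()
        user = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
        if user is None:
            user = {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config file {p} must contain a mapping at top level")
        raw = _deep_merge(raw, user)
    if overrides:
        raw = _deep_merge(raw, overrides)
    return _resolve(raw)
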