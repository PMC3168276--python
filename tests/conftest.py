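import numpy as np
import pytest

from angiofield.config import load_config
from angiofield.ifp import solve_ifp_analytic


@pytest.fixture(scope="session")
def cfg():
    return load_config()


@pytest.fixture(scope="session")
def geom(cfg):
    return cfg.geometry


@pytest.fixture(scope="session")
def default_groups(cfg):
    """Nondimensional groups for both factor families, default tumor column."""
    return {fac: cfg.groups(fac) for fac in ("pro", "anti")}


@pytest.fixture(scope="session")
def no_convection_groups(default_groups):
    return {
        fac: {t: g.with_(K_tilde=0.0) for t, g in block.items()}
        for fac, block in default_groups.items()
    }


@pytest.fixture(scope="session")
def default_pressure(cfg, geom):
    return solve_ifp_analytic(cfg.alpha("tumor"), cfg.alpha("host"), geom)


@pytest.fixture(scope="session")
def zero_pressure(geom):
    return solve_ifp_analytic(0.0, 0.0, geom)


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (for printed-table comparisons)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, sig - 1 - floor(log10(abs(x))))


@pytest.fixture(scope="session")
def reference_table_cells(cfg):
    """Every nondimensional table cell: (computed value, printed value, sig figs)."""
    groups = {fac: cfg.groups(fac) for fac in ("pro", "anti")}
    norm_groups = {fac: cfg.groups(fac, "normalized") for fac in ("pro", "anti")}
    R = cfg.geometry.R
    cells = [
        ("k_p host", groups["pro"]["host"].k_tilde, 80.0, 2),
        ("k_p tumor", groups["pro"]["tumor"].k_tilde, 57.9, 3),
        ("k_a host", groups["anti"]["host"].k_tilde, 73.8, 3),
        ("k_a tumor", groups["anti"]["tumor"].k_tilde, 44.0, 2),
        ("g_p host", groups["pro"]["host"].g_tilde, 80.0, 2),
        ("g_p tumor", groups["pro"]["tumor"].g_tilde, 349.0, 3),
        ("g_a host", groups["anti"]["host"].g_tilde, 73.8, 3),
        ("g_a tumor", groups["anti"]["tumor"].g_tilde, 280.0, 3),
        ("K_p host", groups["pro"]["host"].K_tilde, 12.5, 3),
        ("K_p tumor", groups["pro"]["tumor"].K_tilde, 9.1, 2),
        ("K_a host", groups["anti"]["host"].K_tilde, 15.4, 3),
        ("K_a tumor", groups["anti"]["tumor"].K_tilde, 12.5, 3),
        ("k_p normalized", norm_groups["pro"]["tumor"].k_tilde, 57.9, 3),
        ("g_p normalized", norm_groups["pro"]["tumor"].g_tilde, 349.0, 3),
        ("K_a normalized", norm_groups["anti"]["tumor"].K_tilde, 12.5, 3),
        ("alpha host", cfg.alpha("host"), 2.0, 1),
        ("alpha tumor", cfg.alpha("tumor"), 14.0, 2),
        ("alpha normalized", cfg.alpha("normalized"), 6.0, 1),
        ("pe host", cfg.tissues["host"].effective_pressure, 10.9, 3),
        ("pe tumor", cfg.tissues["tumor"].effective_pressure, 20.0, 2),
        ("pe normalized", cfg.tissues["normalized"].effective_pressure, 20.0, 2),
    ]
    return cells


@pytest.fixture(scope="session")
def therapy_table_expected():
    """(alpha_t, g̃_p^t) → regime label for the six cytotoxic-therapy scenarios."""
    return {
        (2.0, 349.0): "global_angiogenesis",
        (2.0, 279.0): "global_suppression",
        (6.0, 349.0): "global_angiogenesis",
        (6.0, 279.0): "focal_suppression",
        (14.0, 349.0): "focal_suppression",
        (14.0, 279.0): "focal_suppression",
    }
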