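import numpy as np
import pytest

from angiofield.agf import AGFOperator, solve_agf, solve_agf_no_convection_analytic
from angiofield.ifp import solve_ifp_analytic
from angiofield.params import Geometry

# Central proangiogenic/antiangiogenic concentrations for the default tumor
# kinetics without convection, frozen from a brute-force finite-difference
# solve on an 8001-node grid (closed form agrees to ~3e-7).
F_P_CENTER_NOCONV = 6.0103058
F_A_CENTER_NOCONV = 6.3092838


def test_uniform_steady_state(no_convection_groups, zero_pressure, geom):
    """Tumor kinetics equal to host kinetics with no convection leave the
    concentrations at the host steady state everywhere."""
    hostlike = {
        fac: {t: block["host"] for t in ("tumor", "host")}
        for fac, block in no_convection_groups.items()
    }
    field = solve_agf(hostlike, zero_pressure, geom)
    assert np.max(np.abs(field.f_p - 1.0)) < 1e-12
    assert np.max(np.abs(field.f_a - 1.0)) < 1e-12


def test_no_convection_fd_matches_closed_form(no_convection_groups, zero_pressure, geom):
    fd = solve_agf(no_convection_groups, zero_pressure, geom)
    closed = solve_agf_no_convection_analytic(no_convection_groups, geom)
    assert np.max(np.abs(fd.f_p - closed.f_p)) < 1e-4
    assert np.max(np.abs(fd.f_a - closed.f_a)) < 1e-4
    assert closed.f_p[0] == pytest.approx(F_P_CENTER_NOCONV, abs=1e-5)
    assert closed.f_a[0] == pytest.approx(F_A_CENTER_NOCONV, abs=1e-5)


def test_core_concentration_maximal_and_decreasing_outward(no_convection_groups, geom):
    """Factor concentrations are highest in the tumor core and fall toward
    the rim (the overproducing tumor is the source, host tissue the sink)."""
    closed = solve_agf_no_convection_analytic(no_convection_groups, geom)
    J = closed.interface_index
    assert np.argmax(closed.f_p) == 0
    assert np.all(np.diff(closed.f_p[: J + 1]) < 0)


def test_discrete_conservation(default_groups, no_convection_groups, default_pressure, zero_pressure, geom):
    for groups, pressure in ((default_groups, default_pressure), (no_convection_groups, zero_pressure)):
        field = solve_agf(groups, pressure, geom)
        assert field.balance is not None
        for fac, residual in field.balance.items():
            assert residual < 1e-8, f"{fac}: budget defect {residual:.2e}"


def test_no_convection_scheme_is_second_order(no_convection_groups, zero_pressure):
    errs = []
    for n_grid in (251, 501, 1001):
        g = Geometry(4.0, 5.0, n_grid)
        fd = solve_agf(no_convection_groups, zero_pressure.on_grid(g), g)
        closed = solve_agf_no_convection_analytic(no_convection_groups, g)
        errs.append(np.max(np.abs(fd.f_p - closed.f_p)))
    for coarse, fine in zip(errs, errs[1:]):
        assert 3.0 < coarse / fine < 5.0


def test_convection_pushes_factors_into_host_tissue(default_groups, no_convection_groups, default_pressure, geom):
    """Outward interstitial flow carries factors across the rim: host-side
    concentrations rise and the pro/anti imbalance at the boundary widens."""
    conv = solve_agf(default_groups, default_pressure, geom)
    noconv = solve_agf_no_convection_analytic(no_convection_groups, geom)
    # beyond the thin host-side boundary layer (r̃ ≳ 1.2) the convected
    # profiles lie strictly above the diffusion-only ones all the way out
    outside = (conv.r_grid > 1.2) & (conv.r_grid < 4.0)
    assert np.all(conv.f_p[outside] > noconv.f_p[outside])
    assert np.all(conv.f_a[outside] > noconv.f_a[outside])
    # and the pro/anti imbalance at the boundary widens with convection
    J = conv.interface_index
    gap_conv = conv.f_p[J] - conv.f_a[J]
    gap_noconv = noconv.f_p[J] - noconv.f_a[J]
    assert gap_conv > gap_noconv


def test_positivity_and_far_field(default_groups, default_pressure, geom):
    field = solve_agf(default_groups, default_pressure, geom)
    assert np.all(field.f_p > 0) and np.all(field.f_a > 0)
    assert field.f_p[-1] == pytest.approx(1.0) and field.f_a[-1] == pytest.approx(1.0)


def test_high_peclet_triggers_refinement(default_groups, default_pressure):
    coarse = Geometry(4.0, 5.0, 101)
    hot = {
        fac: {t: g.with_(K_tilde=g.K_tilde * 10) for t, g in block.items()}
        for fac, block in default_groups.items()
    }
    with pytest.warns(UserWarning, match="Péclet"):
        field = solve_agf(hot, default_pressure.on_grid(coarse), coarse)
    assert field.r_grid.size > coarse.n_grid  # grid was refined
    assert np.all(field.f_p > 0)


def test_operator_reuses_factorization_across_production(default_groups, default_pressure, geom):
    op = AGFOperator(default_groups["pro"]["tumor"], default_groups["pro"]["host"], default_pressure, geom)
    f_default = op.solve()
    f_same = op.solve(g_tilde_tumor=default_groups["pro"]["tumor"].g_tilde)
    assert np.array_equal(f_default, f_same)
    f_less = op.solve(g_tilde_tumor=279.0)
    assert np.all(f_less[:-1] <= f_default[:-1])  # lower production, lower concentrations
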