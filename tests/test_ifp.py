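import numpy as np
import pytest

from angiofield.ifp import (
    domain_truncation_error,
    solve_ifp_analytic,
    solve_ifp_numeric,
    velocity,
)
from angiofield.params import Geometry

GEOM = Geometry(4.0, 5.0, 2001)

# Center pressure for the nonnormalized-tumor case (alpha_t=14, alpha_h=2),
# frozen from the finite-difference oracle on an 8001-node grid (0.9999956343);
# the closed form agrees to 2e-10.
P_CENTER_14_2 = 0.9999956344


def test_no_sources_gives_zero_field():
    f = solve_ifp_analytic(0.0, 0.0, GEOM)
    assert np.all(f.p_tilde == 0.0)
    assert np.all(f.u_tilde == 0.0)
    n = solve_ifp_numeric(0.0, 0.0, GEOM)
    assert np.max(np.abs(n.p_tilde)) < 1e-12


def test_large_alpha_plateau():
    """With overwhelming transvascular exchange the interior equilibrates with
    the vasculature: p̃(0) → 1."""
    f = solve_ifp_analytic(1e4, 2.0, Geometry(4.0, 5.0, 101))
    assert f.p_tilde[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(f.p_tilde < 1.0 + 1e-15)


def test_center_pressure_matches_fine_grid_oracle():
    a = solve_ifp_analytic(14.0, 2.0, GEOM)
    n = solve_ifp_numeric(14.0, 2.0, GEOM)
    assert a.p_tilde[0] == pytest.approx(P_CENTER_14_2, abs=1e-6)
    assert n.p_tilde[0] == pytest.approx(P_CENTER_14_2, abs=1e-6)


@pytest.mark.parametrize("alpha_t", [2.0, 6.0, 14.0])
def test_analytic_vs_numeric_cross_check(alpha_t):
    a = solve_ifp_analytic(alpha_t, 2.0, GEOM)
    n = solve_ifp_numeric(alpha_t, 2.0, GEOM)
    assert np.max(np.abs(a.p_tilde - n.p_tilde)) < 1e-5


def test_numeric_scheme_is_second_order():
    errs = []
    for n_grid in (501, 1001, 2001):
        g = Geometry(4.0, 5.0, n_grid)
        err = np.max(np.abs(solve_ifp_analytic(14.0, 2.0, g).p_tilde - solve_ifp_numeric(14.0, 2.0, g).p_tilde))
        errs.append(err)
    for coarse, fine in zip(errs, errs[1:]):
        assert 3.0 < coarse / fine < 5.0  # halving h cuts the error ~4x


def test_pressure_and_velocity_continuous_at_interface():
    eps = 1e-9
    a = solve_ifp_analytic(14.0, 2.0, GEOM)
    assert abs(float(a.p_at(1.0 - eps)) - float(a.p_at(1.0 + eps))) < 1e-8
    assert abs(float(a.u_at(1.0 - eps)) - float(a.u_at(1.0 + eps))) < 1e-6
    n = solve_ifp_numeric(14.0, 2.0, GEOM)
    assert n.interface_velocity_jump < 1e-8


def test_unequal_conductivities_match_darcy_flux():
    """With K_h != K_t the velocity jumps so that K·ũ stays continuous."""
    k_ratio = 2.0
    eps = 1e-9
    f = solve_ifp_analytic(14.0, 2.0, GEOM, k_ratio=k_ratio)
    u_in = float(f.u_at(1.0 - eps))
    u_out = float(f.u_at(1.0 + eps))
    assert u_in == pytest.approx(k_ratio * u_out, rel=1e-6)
    assert abs(float(f.p_at(1.0 - eps)) - float(f.p_at(1.0 + eps))) < 1e-8


def test_pressure_strictly_decreasing_inside_domain():
    for alpha_t in (6.0, 14.0):
        f = solve_ifp_analytic(alpha_t, 2.0, GEOM)
        dp = np.diff(f.p_tilde)
        assert np.all(dp[1:] < 0)  # strictly decreasing away from the center
        assert 0.0 <= f.p_tilde.min() and f.p_tilde.max() < 1.0


def test_profile_trends_with_alpha_t():
    """Raising the tumor pressure parameter raises the core plateau, sharpens
    the rim boundary layer, and strengthens the rim velocity peak."""
    p0s, widths, peaks = [], [], []
    for alpha_t in (2.0, 6.0, 14.0):
        f = solve_ifp_analytic(alpha_t, 2.0, GEOM)
        p0s.append(f.p_tilde[0])
        inside = f.r_grid <= 1.0
        above = f.r_grid[inside][f.p_tilde[inside] >= 0.75 * f.p_tilde[0]]
        widths.append(1.0 - above.max())  # rim distance over which p falls below 75% of core
        peaks.append(f.u_tilde.max())
        assert f.r_grid[np.argmax(f.u_tilde)] == pytest.approx(1.0)
    assert p0s == sorted(p0s)
    assert widths == sorted(widths, reverse=True)
    assert peaks == sorted(peaks)


def test_velocity_symmetry_and_dual_path_peak():
    n = solve_ifp_numeric(14.0, 2.0, GEOM)
    assert n.u_tilde[0] == 0.0
    a = solve_ifp_analytic(14.0, 2.0, GEOM)
    # independent route: differentiate the numeric p̃ and compare peak values
    u_fd = velocity(n)
    assert abs(a.u_tilde.max() - u_fd.max()) < 1e-4


def test_degenerate_matching_raises():
    with pytest.raises(ValueError, match="degenerate"):
        solve_ifp_analytic(14.0, 2.0, GEOM, k_ratio=0.0)
    with pytest.raises(ValueError):
        solve_ifp_analytic(-1.0, 2.0, GEOM)


def test_domain_truncation_is_negligible():
    assert domain_truncation_error(14.0, 2.0, Geometry(4.0, 5.0, 1001)) < 1e-6
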