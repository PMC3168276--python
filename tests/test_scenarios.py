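import numpy as np
import pytest

from angiofield.scenarios import (
    ScenarioSpec,
    run_scenario,
    sweep_production_plane,
    cytotoxic_table_presets,
    therapy_presets,
)


def test_default_scenario_is_focal_suppression(cfg):
    result = run_scenario(ScenarioSpec(name="defaults"), cfg)
    assert result.regime == "focal_suppression"
    assert result.pressure.alpha_t == pytest.approx(14.0, abs=0.02)


def test_cytotoxic_table_presets_reproduce_printed_labels(cfg, therapy_table_expected):
    specs = cytotoxic_table_presets(cfg)
    assert len(specs) == 6
    for spec in specs:
        result = run_scenario(spec, cfg)
        alpha_t = round(result.pressure.alpha_t, 6)
        g_p = result.groups["pro"]["tumor"].g_tilde
        assert result.regime == therapy_table_expected[(alpha_t, g_p)], spec.name


def test_cytotoxic_preset_changes_only_proangiogenic_production(cfg):
    specs = {s.name: s for s in cytotoxic_table_presets(cfg)}
    ref = run_scenario(specs["no_treatment_alpha14"], cfg)
    cyto = run_scenario(specs["cytotoxic_alpha14"], cfg)
    assert ref.groups["pro"]["tumor"].g_tilde == 349.0
    assert cyto.groups["pro"]["tumor"].g_tilde == 279.0
    assert ref.groups["anti"]["tumor"].g_tilde == cyto.groups["anti"]["tumor"].g_tilde == 280.0
    assert ref.groups["pro"]["tumor"].k_tilde == cyto.groups["pro"]["tumor"].k_tilde


def test_normalization_presets_reach_alpha_six(cfg):
    by_name = {s.name: s for s in therapy_presets(cfg)}
    for name in ("normalization_lp_sv", "normalization_column"):
        result = run_scenario(by_name[name], cfg)
        assert result.pressure.alpha_t == pytest.approx(6.0, abs=0.01), name


def test_override_couplings(cfg):
    """Changing Lp moves only alpha; pe only the convection parameters;
    K moves both — all derived, never set directly."""
    base = run_scenario(ScenarioSpec(name="base"), cfg)

    lp = run_scenario(ScenarioSpec(name="lp", overrides={"tumor.Lp": 3.6e-7}), cfg)
    assert lp.pressure.alpha_t < base.pressure.alpha_t
    assert lp.groups["pro"]["tumor"].K_tilde == base.groups["pro"]["tumor"].K_tilde

    pe = run_scenario(ScenarioSpec(name="pe", overrides={"global.pe": 30.0}), cfg)
    assert pe.pressure.alpha_t == base.pressure.alpha_t
    assert pe.groups["pro"]["tumor"].K_tilde > base.groups["pro"]["tumor"].K_tilde

    kc = run_scenario(ScenarioSpec(name="k", overrides={"global.K": 5.0e-5}), cfg)
    assert kc.pressure.alpha_t < base.pressure.alpha_t
    assert kc.groups["pro"]["tumor"].K_tilde > base.groups["pro"]["tumor"].K_tilde


def test_rim_activity_grows_with_alpha_and_pe(cfg):
    """The rim activity peak strengthens with alpha_t and, at fixed alpha_t,
    with the effective pressure driving convection."""
    peaks = []
    for spec in cytotoxic_table_presets(cfg):
        if "no_treatment" not in spec.name:
            continue
        result = run_scenario(spec, cfg)
        peaks.append(result.activity.a[-1])
    assert peaks == sorted(peaks)  # presets ordered alpha_t = 2, 6, 14

    pe_peaks = []
    for pe in (10.0, 20.0, 30.0):
        result = run_scenario(ScenarioSpec(name=f"pe{pe}", overrides={"global.pe": pe}), cfg)
        pe_peaks.append(result.activity.a[-1])
    assert pe_peaks == sorted(pe_peaks)


def test_unknown_override_and_failure_name_the_scenario(cfg):
    with pytest.raises(ValueError, match="bad_path"):
        run_scenario(ScenarioSpec(name="oops", overrides={"tumor.bogus_bad_path": 1.0}), cfg)
    with pytest.raises(ValueError, match="oops2"):
        run_scenario(ScenarioSpec(name="oops2", overrides={"tumor.sigma": 3.0}), cfg)


def test_sweep_corners_and_focal_band(cfg):
    m = sweep_production_plane(14.0, n_per_axis=9, base=cfg)
    assert m.labels[-1, 0] == "global_angiogenesis"  # proangiogenic dominance
    assert m.labels[0, -1] == "global_suppression"  # inhibitor dominance
    assert m.label_at(349.0, 280.0) == "focal_suppression"

    m2 = sweep_production_plane(2.0, n_per_axis=9, base=cfg)
    assert m.band_area("focal_suppression") > m2.band_area("focal_suppression")


def test_sweep_boundaries_track_label_changes(cfg):
    m = sweep_production_plane(14.0, n_per_axis=9, base=cfg)
    assert m.boundaries  # at least one regime boundary in the bracketed range
    for pair, pts in m.boundaries.items():
        assert len(pair) == 2 and pts.shape[1] == 2


def test_sweep_consistent_with_full_pipeline(cfg):
    """A sweep cell's label matches an independent end-to-end scenario run at
    the same production values (pressure reuse changes nothing)."""
    m = sweep_production_plane(14.0, n_per_axis=5, base=cfg)
    t = cfg.tissues["tumor"]
    from angiofield.params import lp_for_alpha

    lp = lp_for_alpha(14.0, cfg.geometry.R, t.SV, t.K)
    for i, j in ((0, 0), (2, 2), (4, 0), (0, 4)):
        spec = ScenarioSpec(
            name=f"cell{i}{j}",
            overrides={
                "tumor.Lp": lp,
                "tumor.g_p_tilde": float(m.g_p_axis[i]),
                "tumor.g_a_tilde": float(m.g_a_axis[j]),
            },
        )
        assert run_scenario(spec, cfg).regime == m.labels[i, j]


def test_therapy_preset_list(cfg):
    specs = therapy_presets(cfg)
    names = [s.name for s in specs]
    assert len(names) == len(set(names)) == 10
    assert sum(n.startswith(("no_treatment", "cytotoxic")) for n in names) == 6
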