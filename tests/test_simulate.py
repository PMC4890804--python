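import numpy as np
import pandas as pd
import pytest

from zratio import diffexp, page, pipeline
from zratio.simulate import (
    SimulationConfig,
    design_from_config,
    recovery_effect_layout,
    simulate_behavior,
    simulate_expression,
    simulate_gene_sets,
    simulate_qpcr,
)


def test_same_seed_gives_identical_matrices():
    cfg = SimulationConfig(n_probes=200, seed=42)
    m1, t1 = simulate_expression(cfg)
    m2, t2 = simulate_expression(SimulationConfig(n_probes=200, seed=42))
    pd.testing.assert_frame_equal(m1.data, m2.data)
    pd.testing.assert_frame_equal(t1, t2)


def test_different_seed_changes_matrix():
    m1, _ = simulate_expression(SimulationConfig(n_probes=50, seed=1))
    m2, _ = simulate_expression(SimulationConfig(n_probes=50, seed=2))
    assert not np.allclose(m1.data.to_numpy(), m2.data.to_numpy())


def test_design_matches_config_groups():
    cfg = SimulationConfig(n_probes=10)
    design = design_from_config(cfg)
    assert design.groups == ["sham", "PHEN", "mTBI", "mTBI_PHEN"]
    assert design.group_sizes() == {g: 5 for g in design.groups}


def test_truth_table_records_folds_and_directions():
    effects = {"P00001": {"mTBI": 2.5}, "P00002": {"mTBI": 0.4, "PHEN": 2.0}}
    cfg = SimulationConfig(n_probes=100, effects=effects, seed=0)
    _, truth = simulate_expression(cfg)
    assert truth.loc["P00001", "direction_mTBI"] == "up"
    assert truth.loc["P00002", "direction_mTBI"] == "down"
    assert truth.loc["P00002", "direction_PHEN"] == "up"
    assert truth.loc["P00001", "fold_PHEN"] == 1.0


def test_planted_probe_outside_range_rejected():
    with pytest.raises(ValueError, match="outside"):
        SimulationConfig(n_probes=10, effects={"P99999": {"mTBI": 2.0}})


def test_planted_fold_raises_group_mean_intensity():
    cfg = SimulationConfig(
        n_probes=500,
        effects={"P00007": {"mTBI": 4.0}},
        noise_sd=0.02,
        array_scale_sd=0.0,
        array_offset_sd=0.0,
        seed=9,
    )
    m, _ = simulate_expression(cfg)
    design = design_from_config(cfg)
    fc = diffexp.fold_change(m, design, "mTBI", "sham")
    assert fc.loc["P00007"] == pytest.approx(4.0, rel=0.15)


def test_array_affine_effects_removed_by_zscoring():
    base = dict(n_probes=300, seed=11, noise_sd=0.1)
    with_eff, _ = simulate_expression(
        SimulationConfig(**base, array_scale_sd=0.08, array_offset_sd=0.3)
    )
    without, _ = simulate_expression(
        SimulationConfig(**base, array_scale_sd=0.0, array_offset_sd=0.0)
    )
    z_with = diffexp.zscore_normalize(diffexp.log_transform(with_eff))
    z_without = diffexp.zscore_normalize(diffexp.log_transform(without))
    np.testing.assert_allclose(
        z_with.data.to_numpy(), z_without.data.to_numpy(), atol=1e-9
    )


def test_recovery_layout_covers_expected_patterns():
    effects, regions = recovery_effect_layout()
    assert len(effects) == 100
    labels = {lab for key, _ in regions.values() for lab in key}
    assert labels == {"mTBI_vs_sham", "mTBI_PHEN_vs_sham", "PHEN_vs_sham"}
    folds = {f for e in effects.values() for f in e.values()}
    assert folds == {2.0, 0.5}


def test_planted_mTBI_probe_lands_in_exclusive_venn_region():
    effects = {"P00010": {"mTBI": 2.5}}
    cfg = SimulationConfig(n_probes=800, effects=effects, noise_sd=0.05, seed=13)
    m, _ = simulate_expression(cfg)
    design = design_from_config(cfg)
    tables = pipeline.run_comparisons(
        m, design, [("mTBI", "sham"), ("mTBI_PHEN", "sham"), ("PHEN", "sham")]
    )
    from zratio.venn import partition_signed

    part = partition_signed(pipeline.significant_lists(tables))
    assert "P00010" in part.genes({"mTBI_vs_sham"}, "up")


# ----------------------------------------------------------------- gene sets

def test_gene_sets_enriched_sets_score_high():
    effects, _ = recovery_effect_layout()
    cfg = SimulationConfig(n_probes=2000, effects=effects, noise_sd=0.05, seed=17)
    m, truth = simulate_expression(cfg)
    design = design_from_config(cfg)
    sets, set_truth = simulate_gene_sets(
        truth, cfg.probe_ids(), group="mTBI", n_sets=12, n_enriched=2,
        set_size=20, seed=17,
    )
    z = diffexp.zscore_normalize(diffexp.log_transform(m))
    zr = diffexp.zratio(z, design, "mTBI", "sham")["z_ratio"]
    result = page.page_enrichment(zr, sets, min_size=10)
    for name, row in set_truth.iterrows():
        z_page = result.loc[name, "z_page"]
        if row["enriched"]:
            assert abs(z_page) > 3
            assert result.loc[name, "direction"] == row["direction"]
        else:
            assert abs(z_page) < 3


def test_gene_sets_empty_spec_gives_empty_collection():
    truth = pd.DataFrame()
    sets, set_truth = simulate_gene_sets(
        truth, [f"P{i:05d}" for i in range(1, 101)], group="mTBI",
        n_sets=0, n_enriched=0, set_size=5, seed=0,
    )
    assert len(sets) == 0
    assert set_truth.empty


# --------------------------------------------------------------------- qpcr

def test_qpcr_reference_gene_ratio_fixed_at_one():
    records = simulate_qpcr({"Arc": 1.8}, sd_ct=0.0, seed=0)
    gapdh = records[records["gene"] == "Gapdh"]
    assert gapdh.groupby("group")["Ct"].mean().nunique() == 1


def test_qpcr_determinism():
    a = simulate_qpcr({"Arc": 1.8}, sd_ct=0.2, seed=5)
    b = simulate_qpcr({"Arc": 1.8}, sd_ct=0.2, seed=5)
    pd.testing.assert_frame_equal(a, b)


# ------------------------------------------------------------------ behavior

def test_behavior_index_mean_zero_balances_times():
    table = simulate_behavior({"g": 0.0}, sd=0.1, n_per_group=500, seed=21)
    assert table["t_novel"].mean() == pytest.approx(
        table["t_familiar"].mean(), rel=0.05
    )


def test_behavior_total_time_fixed():
    table = simulate_behavior({"g": 0.3}, sd=0.2, n_per_group=20, seed=22,
                              total_time=40.0)
    np.testing.assert_allclose(
        (table["t_novel"] + table["t_familiar"]).to_numpy(), 40.0
    )
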