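"""Synthetic data generator: construction rules, determinism, decay model."""

import numpy as np
import pandas as pd
import pytest

import dryseed as ds
from dryseed.simulate import _group_effects
from dryseed.taggit import TAGGIT_SCHEMA


class TestGenerateAnnotation:
    def test_row_counts_and_control_flags(self):
        cfg = ds.SimulationConfig(n_genes=10, n_control_probes=2, rng_seed=0)
        ann, truth = ds.generate_annotation(cfg)
        assert len(ann) == 12
        assert ann["is_control"].sum() == 2
        assert len(truth.table) == 12
        assert (ann.index == truth.table.index).all()

    def test_category_members_carry_keyword_in_description(self, small_dataset):
        ann, truth, _ = small_dataset
        for gid, cats in truth.table["taggit_categories"].items():
            if cats:
                desc = ann.loc[gid, "description"].lower()
                kws = [kw for c in cats for kw in TAGGIT_SCHEMA[c]]
                assert any(kw in desc for kw in kws)

    def test_same_seed_gives_identical_tables(self):
        cfg = ds.SimulationConfig(n_genes=200, n_control_probes=4, rng_seed=5)
        a1, t1 = ds.generate_annotation(cfg)
        a2, t2 = ds.generate_annotation(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_nonpositive_n_genes_rejected(self):
        with pytest.raises(ValueError):
            ds.SimulationConfig(n_genes=0)

    def test_truth_invariant_de_iff_nonzero_logfc(self, small_dataset):
        _, truth, _ = small_dataset
        for cname, _, _ in truth.contrasts:
            lfc, de = truth.true_logfc(cname), truth.is_de(cname)
            assert ((lfc != 0) == de).all()


class TestGenerateExpression:
    def test_zero_noise_reproduces_planted_logfc_exactly(self):
        cfg = ds.SimulationConfig(
            n_genes=300, n_control_probes=3, replicate_noise_sd=0.0, rng_seed=2
        )
        _, truth = ds.generate_annotation(cfg)
        mat = ds.generate_expression(cfg, truth)
        for cname, a, b in cfg.contrasts:
            mean_a = mat.values[mat.group_columns(a)].mean(axis=1)
            mean_b = mat.values[mat.group_columns(b)].mean(axis=1)
            np.testing.assert_allclose(
                (mean_a - mean_b).to_numpy(), truth.true_logfc(cname).to_numpy(), atol=1e-12
            )

    def test_planted_sign_imbalance_matches_pi_down(self):
        cfg = ds.SimulationConfig(n_genes=20000, n_control_probes=2, pi_down=0.65, rng_seed=3)
        _, truth = ds.generate_annotation(cfg)
        lfc = truth.true_logfc("DvsWT")
        de = lfc[lfc != 0]
        frac_down = (de < 0).mean()
        assert frac_down == pytest.approx(0.65, abs=0.03)

    def test_planted_de_count_forced_by_fraction(self):
        cfg = ds.SimulationConfig(n_genes=1000, n_control_probes=2, frac_de_per_contrast=0.05, rng_seed=4)
        _, truth = ds.generate_annotation(cfg)
        assert int(truth.is_de("DvsWT").sum()) == 50

    def test_mismatched_truth_rejected(self, small_config, small_dataset):
        _, truth, _ = small_dataset
        other = ds.SimulationConfig(n_genes=50, n_control_probes=1)
        with pytest.raises(ValueError):
            ds.generate_expression(other, truth)

    def test_metadata_carries_groups_and_replicates(self, small_dataset):
        _, _, mat = small_dataset
        assert set(mat.samples["group"]) == {"WT", "D", "AR", "GID1bOE"}
        assert (mat.samples.groupby("group").size() == 3).all()


class TestDecaySimulator:
    def test_abundance_halves_at_one_half_life(self):
        out = ds.simulate_dry_storage_decay(np.array([100.0]), np.array([6.0]), t=6.0)
        assert out[0] == pytest.approx(50.0)

    def test_t_zero_is_identity(self):
        a0 = np.array([3.0, 7.0, 11.0])
        out = ds.simulate_dry_storage_decay(a0, np.array([1.0, 5.0, 20.0]), t=0.0)
        np.testing.assert_array_equal(out, a0)

    def test_renormalized_log_ratio_increasing_in_half_life(self):
        # equal starting abundances, half-lives 1..24 h, 12 h storage:
        # the apparent log2 change vs t=0 must rise with stability and be
        # positive for the most stable transcript
        hl = np.arange(1.0, 25.0)
        a0 = np.full_like(hl, 10.0)
        decayed = ds.simulate_dry_storage_decay(a0, hl, t=12.0, renormalize=True)
        log_ratio = np.log2(decayed / a0)
        assert (np.diff(log_ratio) > 0).all()
        assert log_ratio[-1] > 0

    def test_renormalization_conserves_total_mass(self):
        rng = np.random.default_rng(0)
        a0 = rng.uniform(1, 100, size=50)
        hl = rng.uniform(0.5, 30, size=50)
        decayed = ds.simulate_dry_storage_decay(a0, hl, t=24.0, renormalize=True)
        assert decayed.sum() == pytest.approx(a0.sum(), rel=1e-12)

    @pytest.mark.parametrize("t,hl", [(-1.0, [2.0]), (5.0, [0.0]), (5.0, [-3.0])])
    def test_invalid_time_or_half_life_rejected(self, t, hl):
        with pytest.raises(ValueError):
            ds.simulate_dry_storage_decay(np.array([1.0]), np.array(hl), t=t)


class TestGenerateCtTable:
    def test_noiseless_ct_shift_is_minus_log2_fold(self, small_config, small_dataset):
        _, truth, _ = small_dataset
        ct = ds.generate_ct_table(small_config, truth, noise_sd_cycles=0.0)
        effects = _group_effects(small_config, truth)
        target = sorted(set(ct.data["gene"]) - {ct.reference_gene})[0]
        tgt = ct.data[ct.data["gene"] == target]
        base = tgt.loc[tgt["condition"] == ct.calibrator, "ct"].iloc[0]
        for cond in set(tgt["condition"]) - {ct.calibrator}:
            shift = tgt.loc[tgt["condition"] == cond, "ct"].iloc[0] - base
            fold = 2.0 ** (effects.loc[target, cond] - effects.loc[target, ct.calibrator])
            assert shift == pytest.approx(-np.log2(fold), abs=1e-12)

    def test_ddct_roundtrip_recovers_planted_fold(self, small_config, small_dataset):
        _, truth, _ = small_dataset
        noise = 0.05
        ct = ds.generate_ct_table(small_config, truth, noise_sd_cycles=noise)
        effects = _group_effects(small_config, truth)
        target = sorted(set(ct.data["gene"]) - {ct.reference_gene})[0]
        rel = ds.delta_delta_ct(ct, target)
        for cond, mean_rq in rel.summary["mean_rq"].items():
            planted = 2.0 ** (effects.loc[target, cond] - effects.loc[target, ct.calibrator])
            # log2 error bounded by a few combined noise sd
            assert abs(np.log2(mean_rq) - np.log2(planted)) < 2 * noise * 2

    def test_unity_fold_gives_rq_one_noiseless(self, small_config, small_dataset):
        _, truth, _ = small_dataset
        flat_gene = truth.table.index[
            (~truth.table["is_control"])
            & (truth.table[[c for c in truth.table.columns if c.startswith("de_")]] == False).all(axis=1)  # noqa: E712
        ][1]
        ct = ds.generate_ct_table(small_config, truth, targets=[flat_gene], noise_sd_cycles=0.0)
        rel = ds.delta_delta_ct(ct, flat_gene)
        np.testing.assert_allclose(rel.summary["mean_rq"].to_numpy(), 1.0, atol=1e-12)


class TestGenerateGenesets:
    def test_taggit_map_has_26_categories(self, small_genesets):
        taggit_map, *_ = small_genesets
        assert len(taggit_map.ids) == 26

    def test_tf_members_listed_under_their_family(self, small_dataset, small_genesets):
        _, truth, _ = small_dataset
        _, tf_db, *_ = small_genesets
        fams = truth.table.loc[truth.table["tf_family"] != "", "tf_family"]
        assert (tf_db.loc[fams.index, "family"] == fams).all()

    def test_half_life_table_excludes_unscored(self, small_dataset, small_genesets):
        _, truth, _ = small_dataset
        *_, half_lives = small_genesets
        tt = truth.table[~truth.table["is_control"]]
        assert len(half_lives) == tt["half_life_h"].notna().sum()
        assert (half_lives > 0).all()

    def test_confidence_levels_partition_targets(self, small_genesets):
        _, _, tft_targets, _, _ = small_genesets
        for sets in tft_targets.values():
            assert sets["all"] == sets["confirmed"] | sets["unconfirmed"]
            assert not (sets["confirmed"] & sets["unconfirmed"])
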