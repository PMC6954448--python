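"""ΔΔCt quantification, uridylation ratios, polysome spike-in normalization."""

import numpy as np
import pandas as pd
import pytest

from mztdecay.quant import (polysome_normalize, relative_level,
                            relative_levels, uridylation_ratio,
                            validate_ct_table)
from mztdecay.simulate import (SimConfig, generate_expression,
                               generate_polysome, generate_qpcr)


def _ct_rows(rows):
    frame = pd.DataFrame(rows)
    frame["condition"] = frame.get("condition", "control")
    frame["reference_gene"] = frame.get("reference_gene", "Gapdh")
    frame["replicate"] = frame.get("replicate", 1)
    return validate_ct_table(frame)


def _simple_table(ct_target, ct_ref=20.0, mode="random"):
    ref_gene = "Gapdh" if mode == "random" else "Gfp"
    return _ct_rows([
        {"sample": "s", "gene": "tgt", "primer_mode": mode, "ct": ct_target},
        {"sample": "s", "gene": ref_gene, "primer_mode": mode, "ct": ct_ref},
    ])


class TestRelativeLevel:
    def test_equal_ct_gives_level_one(self):
        assert relative_level(_simple_table(20.0), "tgt", "s") == 1.0

    def test_one_cycle_later_halves_level(self):
        assert relative_level(_simple_table(21.0), "tgt", "s") == 0.5

    def test_replicates_averaged_before_delta_ct(self):
        table = _ct_rows([
            {"sample": "s", "gene": "tgt", "primer_mode": "random",
             "ct": 19.0, "replicate": 1},
            {"sample": "s", "gene": "tgt", "primer_mode": "random",
             "ct": 21.0, "replicate": 2},
            {"sample": "s", "gene": "Gapdh", "primer_mode": "random",
             "ct": 20.0, "replicate": 1},
        ])
        assert relative_level(table, "tgt", "s") == 1.0

    def test_reference_invariance_under_ct_shift(self):
        # adding a constant to every Ct of a sample cancels in ΔCt
        base = _simple_table(18.5)
        shifted = base.copy()
        shifted["ct"] += 3.7
        assert relative_level(base, "tgt", "s") == pytest.approx(
            relative_level(shifted, "tgt", "s"), rel=1e-12)

    def test_missing_reference_rejected(self):
        table = _ct_rows([{"sample": "s", "gene": "tgt",
                           "primer_mode": "random", "ct": 20.0}])
        with pytest.raises(ValueError, match="no Ct"):
            relative_level(table, "tgt", "s")

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _simple_table(-1.0)


class TestRoundTrip:
    def test_zero_noise_recovers_planted_levels_exactly(self):
        config = SimConfig(genes_per_archetype=5, replicates=2,
                           noise_sd_log2=0.0, ct_noise_sd=0.0, seed=9)
        _, truth = generate_expression(config)
        ct = generate_qpcr(config, truth)
        for row in truth.qpcr_expression.itertuples():
            level = relative_level(ct, row.gene, row.sample)
            assert level == pytest.approx(row.level, rel=1e-12)

    def test_noisy_recovery_within_15_percent(self):
        # Gaussian Ct noise makes any single assay unbounded in the extreme
        # tail; the 15% accuracy is asserted on the error distribution
        config = SimConfig(genes_per_archetype=5, replicates=2,
                           noise_sd_log2=0.0, ct_noise_sd=0.1, seed=9)
        _, truth = generate_expression(config)
        ct = generate_qpcr(config, truth)
        rel_errors = []
        for row in truth.qpcr_expression.itertuples():
            level = relative_level(ct, row.gene, row.sample)
            rel_errors.append(abs(level - row.level) / row.level)
        assert np.median(rel_errors) < 0.15
        assert np.percentile(rel_errors, 95) < 0.15

    def test_fold_vs_control_means_one_in_control_group(self):
        config = SimConfig(genes_per_archetype=5, replicates=2,
                           noise_sd_log2=0.0, ct_noise_sd=0.0, seed=9)
        _, truth = generate_expression(config)
        ct = generate_qpcr(config, truth)
        levels = relative_levels(ct, control_condition="WT")
        control = levels[levels["condition"] == "WT"]
        means = control.groupby("gene")["fold_vs_control"].mean()
        assert np.allclose(means, 1.0)


class TestUridylation:
    def test_reference_parity_gives_ratio_one(self):
        table = pd.concat([_simple_table(20.0, mode="random"),
                           _simple_table(20.0, mode="oligo_dA")])
        assert uridylation_ratio(table, "tgt", "s") == 1.0

    def test_halved_oligo_da_level_halves_ratio(self):
        table = pd.concat([_simple_table(20.0, mode="random"),
                           _simple_table(21.0, mode="oligo_dA")])
        assert uridylation_ratio(table, "tgt", "s") == 0.5

    def test_planted_two_cell_uridylation_rise_recovered(self):
        # Z-decay transcripts: three-fold uridylation increase at two-cell
        config = SimConfig(genes_per_archetype=5, replicates=2,
                           noise_sd_log2=0.0, ct_noise_sd=0.0, seed=9)
        _, truth = generate_expression(config)
        ct = generate_qpcr(config, truth)
        gene = truth.archetype.index[truth.archetype == "Z-decay-ZGA-dep"][0]
        rise = (uridylation_ratio(ct, gene, "WT.two-cell")
                / uridylation_ratio(ct, gene, "WT.zygote"))
        assert rise == pytest.approx(3.0, rel=1e-9)

    def test_tut47_depletion_lowers_two_cell_uridylation(self):
        config = SimConfig(genes_per_archetype=5, replicates=2,
                           noise_sd_log2=0.0, ct_noise_sd=0.0, seed=9)
        _, truth = generate_expression(config)
        ct = generate_qpcr(config, truth)
        gene = truth.archetype.index[truth.archetype == "Z-decay-ZGA-dep"][0]
        wt = uridylation_ratio(ct, gene, "WT.two-cell")
        kd = uridylation_ratio(ct, gene, "siTut47.two-cell")
        assert kd < wt

    def test_missing_primer_mode_rejected(self):
        table = _simple_table(20.0, mode="random")
        with pytest.raises(ValueError, match="no Ct"):
            uridylation_ratio(table, "tgt", "s")


class TestPolysomeNormalize:
    def test_spikein_row_becomes_one_and_scales_sample(self):
        values = pd.DataFrame({"s1": [4.0, 2.0], "s2": [9.0, 3.0]},
                              index=["g1", "mCherry"])
        result = polysome_normalize(values)
        assert list(result.loc["mCherry"]) == [1.0, 1.0]
        assert list(result.loc["g1"]) == [2.0, 3.0]

    def test_idempotent(self):
        values = pd.DataFrame({"s1": [4.0, 2.0]}, index=["g1", "mCherry"])
        once = polysome_normalize(values)
        pd.testing.assert_frame_equal(once, polysome_normalize(once))

    def test_zero_spikein_rejected(self):
        values = pd.DataFrame({"s1": [4.0, 0.0]}, index=["g1", "mCherry"])
        with pytest.raises(ValueError):
            polysome_normalize(values)

    def test_planted_binding_difference_recovered_at_zero_noise(self):
        config = SimConfig(genes_per_archetype=5, replicates=2,
                           noise_sd_log2=0.0, ct_noise_sd=0.0, seed=9)
        _, truth = generate_expression(config)
        poly = generate_polysome(config, truth)
        normalized = polysome_normalize(poly)
        m_gene = truth.archetype.index[truth.archetype == "M-decay"][0]
        z_gene = truth.archetype.index[
            truth.archetype == "Z-decay-ZGA-dep"][0]
        # capture efficiency cancels: GV/MII ratio equals planted 0.8/0.2
        m_ratio = (normalized.loc[m_gene, "polysome.GV.r1"]
                   / normalized.loc[m_gene, "polysome.MII.r1"])
        z_ratio = (normalized.loc[z_gene, "polysome.GV.r1"]
                   / normalized.loc[z_gene, "polysome.MII.r1"])
        assert m_ratio == pytest.approx(4.0, rel=1e-9)
        assert z_ratio == pytest.approx(0.25, rel=1e-9)
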