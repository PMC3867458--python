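"""Generators: determinism, injected truth bookkeeping, null behaviour."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pparscreen import simulate
from pparscreen.config import SimConfig
from pparscreen.errors import ConfigError


class TestTranscriptome:
    def test_deterministic_by_seed(self):
        cfg = SimConfig(seed=1, n_genes=5, n_affected_down=0, n_affected_up=0)
        a = simulate.generate_transcriptome(cfg)
        b = simulate.generate_transcriptome(cfg)
        assert a["id"].tolist() == ["t0001", "t0002", "t0003", "t0004", "t0005"]
        pd.testing.assert_frame_equal(a, b)

    def test_zero_genes_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genes=0, n_affected_down=0, n_affected_up=0)

    def test_gc_fraction_near_half(self):
        # uniform base model: GC of 100 x 1000 bases is Binomial(1e5, 0.5);
        # the 0.45-0.55 band is > 30 sigma wide
        cfg = SimConfig(seed=7, n_genes=100, n_affected_down=0, n_affected_up=0)
        seqs = "".join(simulate.generate_transcriptome(cfg)["sequence"])
        gc = sum(seqs.count(b) for b in "GC") / len(seqs)
        assert 0.45 < gc < 0.55


class TestTagPairs:
    @pytest.fixture
    def transcripts(self):
        cfg = SimConfig(seed=2, n_genes=10, n_affected_down=0, n_affected_up=0)
        return simulate.generate_transcriptome(cfg)

    def test_no_decoys_all_have_source(self, transcripts):
        pairs = simulate.generate_tag_pairs(transcripts, decoy_fraction=0.0, seed=3)
        assert (pairs["source_transcript"] != "").all()

    def test_uncorrupted_pairs_match_source_exactly(self, transcripts):
        pairs = simulate.generate_tag_pairs(transcripts, mismatch_rate=0.0,
                                            n_rate=0.0, seed=3, tag_length=20)
        seq_of = dict(zip(transcripts["id"], transcripts["sequence"]))
        for _, p in pairs.iterrows():
            seq = seq_of[p["source_transcript"]]
            assert p["tag1"] == seq[p["pos1"]:p["pos1"] + 20]
            assert p["tag2"] == simulate.revcomp(seq[p["pos2"]:p["pos2"] + 20])

    def test_heavy_n_masking_flagged_as_expected_filtered(self, transcripts):
        # n_rate high enough that pairs collect >5 Ns must be pre-flagged
        pairs = simulate.generate_tag_pairs(transcripts, n_rate=0.5, seed=4,
                                            tag_length=20)
        heavy = pairs[(pairs["tag1"].str.count("N")
                       + pairs["tag2"].str.count("N")) > 5]
        assert len(heavy) > 0
        assert heavy["expected_filtered"].all()


class TestCountExperiment:
    def test_null_config_centres_log_fold_at_zero(self, null_sim):
        table, _ = simulate.generate_count_experiment(null_sim)
        detected = table[(table["Co"] > 0) & (table["MO"] > 0)]
        logfold = np.log((detected["MO"] + 0.5) / (detected["Co"] + 0.5))
        assert abs(logfold.median()) < 0.05

    def test_library_scale_shifts_median(self):
        cfg = SimConfig(seed=5, n_genes=2000, n_affected_down=0,
                        n_affected_up=0, library_scale=0.8)
        table, truth = simulate.generate_count_experiment(cfg)
        assert truth.library_scale == 0.8
        ratio = np.median(table["MO"]) / np.median(table["Co"])
        assert abs(ratio - 0.8) < 0.08  # within 10% of the injected factor

    def test_affected_genes_recorded(self):
        cfg = SimConfig(seed=6, n_genes=500, n_affected_down=100,
                        n_affected_up=0, effect_fold_range=(4.0, 4.0))
        table, truth = simulate.generate_count_experiment(cfg)
        assert len(truth.affected_genes) == 100
        assert set(truth.affected_genes) <= set(table.index)
        assert all(abs(f - 0.25) < 1e-12 for f in truth.affected_genes.values())


class TestAmplificationCurves:
    @pytest.mark.parametrize("efficiency", [2.0, 1.8])
    def test_noise_free_exponential_slope(self, efficiency):
        cfg = SimConfig(seed=8, n_genes=10, n_affected_down=0, n_affected_up=0,
                        curve_noise_sd=0.0,
                        true_efficiencies={"p": efficiency})
        curves, truth = simulate.generate_amplification_curves(cfg, 2)
        well = curves[curves["well_id"] == curves["well_id"].iloc[0]]
        y = well["fluorescence"].to_numpy() - cfg.curve_baseline
        # pre-saturation phase: below 1% of fmax but above numerical noise
        sel = (y > 1e-6 * cfg.fmax) & (y < 0.01 * cfg.fmax)
        fit = stats.linregress(well["cycle"].to_numpy()[sel], np.log10(y[sel]))
        assert fit.slope == pytest.approx(np.log10(efficiency), abs=2e-3)

    def test_truth_recorded_per_well(self):
        cfg = SimConfig(seed=9, n_genes=10, n_affected_down=0, n_affected_up=0,
                        curve_noise_sd=0.01, true_efficiencies={"p": 1.9})
        curves, truth = simulate.generate_amplification_curves(cfg, 8)
        assert len(truth) == 8
        assert set(truth["well_id"]) == set(curves["well_id"])
        assert (truth["true_efficiency"] == 1.9).all()


class TestChipExperiment:
    def test_percent_input_100_gives_equal_cts(self):
        cfg = SimConfig(seed=10, n_genes=10, n_affected_down=0, n_affected_up=0,
                        true_percent_input={("g1", "H3K27me3"): 100.0},
                        chip_ct_noise_sd=0.0)
        meas, truth = simulate.generate_chip_experiment(cfg)
        row = meas.iloc[0]
        assert row["Ct_sample"] == pytest.approx(row["Ct_input"], abs=1e-9)

    def test_percent_input_25_with_e2_is_two_cycles(self):
        # inverting P = E**(dCt)*100 at E=2, P=25 gives dCt = -2
        cfg = SimConfig(seed=10, n_genes=10, n_affected_down=0, n_affected_up=0,
                        true_percent_input={("g1", "H3K27me3"): 25.0},
                        chip_ct_noise_sd=0.0)
        meas, _ = simulate.generate_chip_experiment(cfg)
        row = meas.iloc[0]
        assert row["Ct_sample"] - row["Ct_input"] == pytest.approx(2.0, abs=1e-9)


class TestTimecourse:
    def test_null_burst_fraction_gives_no_inductions(self):
        cfg = SimConfig(seed=11, n_genes=500, n_affected_down=0,
                        n_affected_up=0, burst_gene_fraction=0.0,
                        timecourse_noise_sd=0.02)
        tc, meta, truth = simulate.generate_timecourse(cfg)
        assert truth.burst_genes == set()
        i = list(tc.columns).index(cfg.gastrula_transition[0])
        ratio = tc.iloc[:, i + 1] / tc.iloc[:, i]
        assert (ratio >= 4).sum() == 0

    def test_burst_genes_jump_and_persist(self):
        cfg = SimConfig(seed=12, n_genes=500, n_affected_down=0,
                        n_affected_up=0, burst_gene_fraction=0.1,
                        burst_fold=8.0, timecourse_noise_sd=0.02)
        tc, meta, truth = simulate.generate_timecourse(cfg)
        assert len(truth.burst_genes) == 50
        stages = list(tc.columns)
        i = stages.index(cfg.gastrula_transition[0])
        sub = tc.loc[sorted(truth.burst_genes)]
        ratio = sub.iloc[:, i + 1] / sub.iloc[:, i]
        assert (ratio >= 4).all()
        # induced level is maintained: >= 50% of the post-burst peak later on
        peak = sub.iloc[:, i + 1]
        for s in range(i + 2, len(stages)):
            assert (sub.iloc[:, s] >= 0.5 * peak - 1e-9).all()


class TestOrthologStates:
    def test_null_odds_ratio_association_absent(self):
        cfg = SimConfig(seed=13, n_genes=20, n_affected_down=0, n_affected_up=0,
                        k27_odds_ratio=1.0, k27_baseline_prob=0.3,
                        n_promoted_genes=300, n_control_genes=300)
        states, truth = simulate.generate_ortholog_states(cfg)
        df = pd.DataFrame({"k27": pd.Series(truth.gene_k27_state),
                           "pro": pd.Series(truth.gene_promoted)})
        table = pd.crosstab(df["pro"], df["k27"]).to_numpy()
        _, p = stats.fisher_exact(table)
        assert p > 0.01  # no detectable association at the null

    def test_full_conservation_means_species_agree(self):
        cfg = SimConfig(seed=14, n_genes=20, n_affected_down=0, n_affected_up=0,
                        conservation_prob=1.0)
        states, _ = simulate.generate_ortholog_states(cfg)
        for gene, grp in states.groupby("gene_id"):
            assert grp["k4"].nunique() == 1 and grp["k27"].nunique() == 1

    def test_determinism(self):
        cfg = SimConfig(seed=15, n_genes=20, n_affected_down=0, n_affected_up=0)
        a, _ = simulate.generate_ortholog_states(cfg)
        b, _ = simulate.generate_ortholog_states(cfg)
        pd.testing.assert_frame_equal(a, b)
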