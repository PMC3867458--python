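"""Ct calling, efficiency estimation and relative quantification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pparscreen import qpcr, simulate
from pparscreen.config import SimConfig
from pparscreen.errors import EstimationError, InvalidInputError


def curve_config(seed=1, noise=0.0, efficiencies=None):
    return SimConfig(seed=seed, n_genes=10, n_affected_down=0, n_affected_up=0,
                     curve_noise_sd=noise,
                     true_efficiencies=efficiencies or {"p": 2.0})


def call_all_cts(curves, threshold):
    rows = []
    for well, grp in curves.groupby("well_id"):
        grp = grp.sort_values("cycle")
        rows.append({"well_id": well,
                     "gene_id": grp["primer_id"].iloc[0],
                     "sample_id": grp["sample_id"].iloc[0],
                     "Ct": qpcr.call_ct(grp["cycle"], grp["fluorescence"],
                                        threshold)})
    return pd.DataFrame(rows)


class TestCallCt:
    def test_recovers_known_crossing_cycle(self):
        cfg = curve_config(seed=2)
        curves, truth = simulate.generate_amplification_curves(cfg, 6)
        cts = call_all_cts(curves, 0.1 * cfg.fmax).set_index("well_id")["Ct"]
        for _, t in truth.iterrows():
            assert cts[t["well_id"]] == pytest.approx(t["true_crossing_cycle"],
                                                      abs=0.05)

    def test_threshold_above_maximum_flags_no_amplification(self):
        cfg = curve_config(seed=3)
        curves, _ = simulate.generate_amplification_curves(cfg, 1)
        grp = curves.sort_values("cycle")
        ct = qpcr.call_ct(grp["cycle"], grp["fluorescence"], 10 * cfg.fmax)
        assert np.isnan(ct)

    def test_doubling_template_shifts_ct_by_one_cycle(self):
        # with E = 2, twice the template crosses one cycle earlier
        cycles = np.arange(1, 41)
        fmax, base = 1.0, 0.05

        def curve(f0):
            u = f0 * 2.0 ** cycles
            return base + u / (1 + u / fmax)

        f0 = 1e-7
        ct1 = qpcr.call_ct(cycles, curve(f0), 0.1)
        ct2 = qpcr.call_ct(cycles, curve(2 * f0), 0.1)
        assert ct1 - ct2 == pytest.approx(1.0, abs=0.05)


class TestEstimateEfficiency:
    @pytest.mark.parametrize("efficiency", [2.0, 1.8])
    def test_noise_free_recovery(self, efficiency):
        cfg = curve_config(seed=4, efficiencies={"p": efficiency})
        curves, _ = simulate.generate_amplification_curves(cfg, 4)
        pe = qpcr.estimate_efficiency(curves, "p")
        assert pe.efficiency == pytest.approx(efficiency, abs=0.01)
        assert pe.n_wells_used == 4

    def test_noisy_recovery_within_tolerance(self):
        errors = []
        for seed in range(10):
            cfg = curve_config(seed=seed, noise=0.005, efficiencies={"p": 1.9})
            curves, _ = simulate.generate_amplification_curves(cfg, 8)
            pe = qpcr.estimate_efficiency(curves, "p")
            errors.append(abs(pe.efficiency - 1.9))
        assert max(errors) < 0.05

    def test_invariant_to_fluorescence_rescaling(self):
        cfg = curve_config(seed=5, noise=0.003, efficiencies={"p": 1.85})
        curves, _ = simulate.generate_amplification_curves(cfg, 4)
        scaled = curves.assign(fluorescence=curves["fluorescence"] * 137.0)
        e1 = qpcr.estimate_efficiency(curves, "p").efficiency
        e2 = qpcr.estimate_efficiency(scaled, "p").efficiency
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_hopeless_curves_raise_naming_primer(self):
        rng = np.random.default_rng(0)
        rows = [{"well_id": "w1", "primer_id": "bad", "sample_id": "Co_r1",
                 "cycle": c, "fluorescence": rng.normal(0.5, 0.2)}
                for c in range(1, 41)]
        with pytest.raises(EstimationError, match="bad"):
            qpcr.estimate_efficiency(pd.DataFrame(rows), "bad")


class TestRelativeQuantity:
    def test_equal_cts_give_unit_rq(self):
        rq = qpcr.relative_quantity(pd.Series({"a": 21.0, "b": 21.0}), 1.87)
        assert (rq == 1.0).all()

    def test_one_cycle_below_calibrator_doubles_at_e2(self):
        rq = qpcr.relative_quantity(pd.Series({"a": 19.0, "b": 21.0}), 2.0)
        assert rq["a"] == pytest.approx(2.0)

    def test_one_cycle_above_calibrator_at_e19(self):
        # ΔCt = +1 from the two-sample calibrator mean is +0.5 cycles
        rq = qpcr.relative_quantity(pd.Series({"a": 20.0, "b": 21.0}), 1.9)
        assert rq["b"] == pytest.approx(1.9 ** (-0.5))
        assert rq["b"] / rq["a"] == pytest.approx(1 / 1.9)

    def test_missing_ct_skipped(self):
        rq = qpcr.relative_quantity(pd.Series({"a": 20.0, "b": np.nan}), 2.0)
        assert list(rq.index) == ["a"]


def rq_frame(records):
    return pd.DataFrame(records, columns=["gene_id", "sample_id", "rq"])


class TestNormalizeToReferences:
    def test_constant_references_are_identity_up_to_constant(self):
        table = rq_frame([("eef1a", "s1", 2.0), ("eef1a", "s2", 2.0),
                          ("rpl8", "s1", 2.0), ("rpl8", "s2", 2.0),
                          ("tgt", "s1", 1.0), ("tgt", "s2", 3.0)])
        out = qpcr.normalize_to_references(table).set_index(["gene_id", "sample_id"])
        assert (out.loc[("tgt", "s2"), "normalized_rq"]
                / out.loc[("tgt", "s1"), "normalized_rq"]) == pytest.approx(3.0)

    def test_doubled_references_halve_targets(self):
        table = rq_frame([("eef1a", "s1", 1.0), ("eef1a", "s2", 2.0),
                          ("rpl8", "s1", 1.0), ("rpl8", "s2", 2.0),
                          ("tgt", "s1", 1.0), ("tgt", "s2", 1.0)])
        out = qpcr.normalize_to_references(table).set_index(["gene_id", "sample_id"])
        assert out.loc[("tgt", "s2"), "normalized_rq"] == pytest.approx(0.5)

    def test_geometric_mean_of_unequal_references(self):
        # one reference x4, the other x1: targets divided by sqrt(4) = 2
        table = rq_frame([("eef1a", "s1", 1.0), ("eef1a", "s2", 4.0),
                          ("rpl8", "s1", 1.0), ("rpl8", "s2", 1.0),
                          ("tgt", "s1", 1.0), ("tgt", "s2", 1.0)])
        out = qpcr.normalize_to_references(table).set_index(["gene_id", "sample_id"])
        assert out.loc[("tgt", "s2"), "normalized_rq"] == pytest.approx(0.5)

    def test_idempotent(self):
        table = rq_frame([("eef1a", "s1", 1.3), ("eef1a", "s2", 0.6),
                          ("rpl8", "s1", 0.8), ("rpl8", "s2", 1.9),
                          ("tgt", "s1", 2.0), ("tgt", "s2", 0.4)])
        once = qpcr.normalize_to_references(table)
        again = qpcr.normalize_to_references(
            once.rename(columns={"normalized_rq": "rq"})[
                ["gene_id", "sample_id", "rq"]])
        merged = once.merge(again, on=["gene_id", "sample_id"])
        assert np.allclose(merged["normalized_rq_x"], merged["normalized_rq_y"])

    def test_missing_reference_names_gene(self):
        table = rq_frame([("eef1a", "s1", 1.0), ("tgt", "s1", 1.0)])
        with pytest.raises(InvalidInputError, match="rpl8"):
            qpcr.normalize_to_references(table)


class TestFoldMoVsCo:
    def test_identical_conditions_give_unit_fold(self):
        table = pd.DataFrame([
            ("g", f"{cond}_r{r}", 1.7) for cond in ("Co", "MO")
            for r in (1, 2, 3)], columns=["gene_id", "sample_id", "normalized_rq"])
        folds = qpcr.fold_mo_vs_co(table)
        assert folds["mean_fold"].iloc[0] == pytest.approx(1.0)
        assert folds["sem"].iloc[0] == pytest.approx(0.0)

    def test_single_replicate_has_undefined_sem(self):
        table = pd.DataFrame([("g", "Co_r1", 2.0), ("g", "MO_r1", 1.0)],
                             columns=["gene_id", "sample_id", "normalized_rq"])
        folds = qpcr.fold_mo_vs_co(table)
        assert folds["mean_fold"].iloc[0] == pytest.approx(0.5)
        assert np.isnan(folds["sem"].iloc[0])

    def test_full_roundtrip_recovers_injected_knockdown(self):
        # generator curves -> Ct -> efficiency -> RQ -> reference
        # normalization -> fold: the module's headline property
        cfg = SimConfig(seed=6, n_genes=10, n_affected_down=0, n_affected_up=0,
                        curve_noise_sd=0.005,
                        true_efficiencies={"eef1a": 1.9, "rpl8": 1.95,
                                           "tgt": 1.85})
        curves, _ = simulate.generate_amplification_curves(
            cfg, 8, mo_fold={"eef1a": 1.0, "rpl8": 1.0, "tgt": 0.25})
        cts = call_all_cts(curves, 0.1 * cfg.fmax)
        eff = qpcr.estimate_all_efficiencies(curves)
        rq = qpcr.relative_quantities(cts[["gene_id", "sample_id", "Ct"]], eff)
        normed = qpcr.normalize_to_references(rq)
        folds = qpcr.fold_mo_vs_co(normed).set_index("gene_id")
        assert 0.2 <= folds.loc["tgt", "mean_fold"] <= 0.32
        assert folds.loc["tgt", "n_replicates"] == 4
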