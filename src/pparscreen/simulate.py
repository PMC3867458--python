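"""Synthetic-data generators with injected, recorded ground truth.

Every dataset the analysis stages consume can be generated here with known
truth: which genes carry an injected morpholino effect and at what fold,
the global library-size factor separating the two sequencing libraries,
the per-primer amplification efficiency behind each fluorescence curve,
the true percent-input of each ChIP locus, which genes burst at the
gastrula transition, and the odds ratio tying the H3K27me3 state to
PPARβ-dependent promotion.  Ground truth is emitted alongside the data and
is read only by tests — analysis stages never see it.

Determinism: every generator derives its random stream from
``SimConfig.seed`` plus a fixed per-generator offset, so an identical
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import ConfigError

_BASES = np.array(list("ACGT"))

# fixed per-generator stream offsets so datasets are independent but
# reproducible from a single seed
_STREAM = {
    "transcriptome": 1,
    "tags": 2,
    "counts": 3,
    "curves": 4,
    "chip": 5,
    "timecourse": 6,
    "ortholog": 7,
}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.seed])


@dataclass
class GroundTruth:
    """Injected truth for one simulated experiment suite."""

    affected_genes: dict[str, float] = field(default_factory=dict)
    library_scale: float = 1.0
    burst_genes: set[str] = field(default_factory=set)
    locus_truth: dict[tuple[str, str], float] = field(default_factory=dict)
    gene_k27_state: dict[str, bool] = field(default_factory=dict)
    gene_promoted: dict[str, bool] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "affected_genes": self.affected_genes,
            "library_scale": self.library_scale,
            "burst_genes": sorted(self.burst_genes),
            "locus_truth": {f"{g}|{ab}": v for (g, ab), v in self.locus_truth.items()},
            "gene_k27_state": self.gene_k27_state,
            "gene_promoted": self.gene_promoted,
        }


def gene_ids(n: int, prefix: str = "t") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# transcriptome & tag pairs
# ---------------------------------------------------------------------------

def generate_transcriptome(config: SimConfig) -> pd.DataFrame:
    """Random uniform-composition transcripts: columns ``id``, ``sequence``."""
    rng = _rng(config, "transcriptome")
    ids = gene_ids(config.n_genes)
    seqs = [
        "".join(_BASES[rng.integers(0, 4, size=config.transcript_length)])
        for _ in ids
    ]
    return pd.DataFrame({"id": ids, "sequence": seqs})


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_tag_pairs(
    transcripts: pd.DataFrame,
    n_pairs_per_transcript: int = 2,
    mismatch_rate: float = 0.0,
    n_rate: float = 0.0,
    decoy_fraction: float = 0.0,
    seed: int = 0,
    tag_length: int = 25,
    max_separation: int = 500,
) -> pd.DataFrame:
    """Paired-end tags extracted from transcripts, with provenance.

    Mates are convergent: tag1 is the forward strand at ``pos1`` and tag2
    the reverse complement of the segment at ``pos2``, with the outermost
    span at most ``max_separation`` nt.  Corruption applies substitutions
    at ``mismatch_rate`` and N masking at ``n_rate`` per base; a pair that
    ends up with >5 Ns or >1 substitution in a mate is labelled
    ``expected_filtered``.  Decoys are random sequences with no source.
    """
    for name, rate in [("mismatch_rate", mismatch_rate), ("n_rate", n_rate),
                       ("decoy_fraction", decoy_fraction)]:
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng([_STREAM["tags"], seed])
    rows = []
    pair_no = 0

    def corrupt(tag: str) -> tuple[str, int]:
        arr = np.array(list(tag))
        n_sub = 0
        if mismatch_rate > 0:
            hit = rng.random(len(arr)) < mismatch_rate
            for i in np.where(hit)[0]:
                choices = [b for b in "ACGT" if b != arr[i]]
                arr[i] = choices[rng.integers(0, 3)]
                n_sub += 1
        if n_rate > 0:
            hit = rng.random(len(arr)) < n_rate
            arr[hit] = "N"
        return "".join(arr), n_sub

    for _, trec in transcripts.iterrows():
        seq = trec["sequence"]
        L = len(seq)
        for _ in range(n_pairs_per_transcript):
            pair_no += 1
            if rng.random() < decoy_fraction:
                tag1 = "".join(_BASES[rng.integers(0, 4, size=tag_length)])
                tag2 = "".join(_BASES[rng.integers(0, 4, size=tag_length)])
                rows.append({
                    "pair_id": f"p{pair_no:06d}", "tag1": tag1, "tag2": tag2,
                    "source_transcript": "", "pos1": -1, "pos2": -1,
                    "is_decoy": True, "expected_filtered": False,
                })
                continue
            span = int(rng.integers(2 * tag_length, min(max_separation, L) + 1))
            pos1 = int(rng.integers(0, L - span + 1))
            pos2 = pos1 + span - tag_length
            raw1 = seq[pos1:pos1 + tag_length]
            raw2 = revcomp(seq[pos2:pos2 + tag_length])
            tag1, sub1 = corrupt(raw1)
            tag2, sub2 = corrupt(raw2)
            n_total = tag1.count("N") + tag2.count("N")
            expected_filtered = n_total > 5 or sub1 > 1 or sub2 > 1
            rows.append({
                "pair_id": f"p{pair_no:06d}", "tag1": tag1, "tag2": tag2,
                "source_transcript": trec["id"], "pos1": pos1, "pos2": pos2,
                "is_decoy": False, "expected_filtered": expected_filtered,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count experiment
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # Gamma-Poisson mixture: var = m + dispersion * m^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_count_experiment(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene x {Co, MO} tag-count table plus injected truth.

    Control means are log-normal; MO means are the control mean times the
    injected per-gene fold (1 for the unaffected majority) times the global
    ``library_scale``.  Both columns are negative-binomial samples.
    """
    rng = _rng(config, "counts")
    genes = gene_ids(config.n_genes)
    mu = np.exp(rng.normal(config.mean_log_expression, config.sd_log_expression,
                           config.n_genes))
    folds = np.ones(config.n_genes)
    n_dn, n_up = config.n_affected_down, config.n_affected_up
    affected_idx = rng.choice(config.n_genes, size=n_dn + n_up, replace=False)
    lo, hi = config.effect_fold_range
    folds[affected_idx[:n_dn]] = 1.0 / rng.uniform(lo, hi, n_dn)
    folds[affected_idx[n_dn:]] = rng.uniform(lo, hi, n_up)

    co = _nb_sample(rng, mu, config.nb_dispersion)
    mo = _nb_sample(rng, mu * folds * config.library_scale, config.nb_dispersion)
    table = pd.DataFrame({"Co": co, "MO": mo}, index=pd.Index(genes, name="gene"))

    truth = GroundTruth(
        affected_genes={genes[i]: float(folds[i]) for i in affected_idx},
        library_scale=config.library_scale,
    )
    return table, truth


# ---------------------------------------------------------------------------
# qPCR amplification curves
# ---------------------------------------------------------------------------

def generate_amplification_curves(
    config: SimConfig,
    n_wells_per_primer: int = 8,
    crossing_cycle_range: tuple[float, float] = (18.0, 26.0),
    threshold_fraction: float = 0.1,
    mo_fold: float | Mapping[str, float] = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format curves (well, primer, sample, cycle, fluorescence) + truth.

    Fluorescence follows baseline + u/(1 + u/fmax) with u = F0 * E**cycle
    plus Gaussian noise.  Wells alternate between replicate Co and MO
    samples (sample ids ``Co_r1``, ``MO_r1``, ...); MO wells start from
    ``mo_fold`` times the Co template amount (per primer when a mapping is
    given), so a knock-down fold effect can be injected and recovered.
    The recorded truth holds, per well, the true efficiency, F0, and the
    exact cycle at which the noise-free corrected curve crosses
    ``threshold_fraction * fmax``.
    """
    rng = _rng(config, "curves")
    cycles = np.arange(1, config.n_cycles + 1)
    thr = threshold_fraction * config.fmax
    thr_eff = thr / (1.0 - threshold_fraction)  # invert the saturation at thr
    curve_rows, truth_rows = [], []
    replicate_jitter_sd = 0.2  # cycles; replicate-to-replicate template scatter
    for primer, eff in config.true_efficiencies.items():
        fold = mo_fold[primer] if isinstance(mo_fold, Mapping) else mo_fold
        if fold <= 0:
            raise ConfigError(f"mo_fold for {primer!r} must be > 0")
        primer_c_cross = rng.uniform(*crossing_cycle_range)
        for w in range(n_wells_per_primer):
            well = f"{primer}_w{w + 1:02d}"
            condition = "Co" if w % 2 == 0 else "MO"
            replicate = w // 2 + 1
            jitter = (rng.normal(0.0, replicate_jitter_sd)
                      if config.curve_noise_sd > 0 else 0.0)
            f0 = thr_eff / eff ** (primer_c_cross + jitter)
            if condition == "MO":
                f0 *= fold
            c_cross = math.log(thr_eff / f0) / math.log(eff)
            u = f0 * eff ** cycles
            fluor = config.curve_baseline + u / (1.0 + u / config.fmax)
            if config.curve_noise_sd > 0:
                fluor = fluor + rng.normal(0.0, config.curve_noise_sd, len(cycles))
            sample = f"{condition}_r{replicate}"
            for c, f in zip(cycles, fluor):
                curve_rows.append({
                    "well_id": well, "primer_id": primer, "sample_id": sample,
                    "cycle": int(c), "fluorescence": float(f),
                })
            truth_rows.append({
                "well_id": well, "primer_id": primer, "sample_id": sample,
                "true_efficiency": eff, "true_f0": f0,
                "true_crossing_cycle": c_cross,
                "true_mo_fold": fold,
                "threshold": thr,
            })
    return pd.DataFrame(curve_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# ChIP-qPCR experiment
# ---------------------------------------------------------------------------

def generate_chip_experiment(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """ChIP Ct table generated by inverting the percent-input formula.

    For each (gene, antibody) in ``config.true_percent_input``:
    Ct_sample = Ct_input - log_E(percent/100) + noise, and likewise the
    mock fraction at ``mock_percent_input``.  With E = 2 and a true percent
    input of 25%, the sample trails the input by exactly 2 cycles.
    """
    rng = _rng(config, "chip")
    loci = config.true_percent_input
    if not loci:
        raise ConfigError("config.true_percent_input is empty")
    E = config.chip_efficiency
    rows = []
    truth = GroundTruth(library_scale=config.library_scale)
    for (gene, antibody), pct in loci.items():
        ct_input = config.input_ct_mean + rng.normal(0.0, 0.3)
        noise = lambda: rng.normal(0.0, config.chip_ct_noise_sd) if config.chip_ct_noise_sd > 0 else 0.0
        ct_sample = ct_input - np.log(pct / 100.0) / np.log(E) + noise()
        ct_mock = ct_input - np.log(config.mock_percent_input / 100.0) / np.log(E) + noise()
        mock_kind = "ppar_mo_signal" if antibody == "PPARb" else "empty_beads"
        rows.append({
            "gene_id": gene, "primer_id": f"{gene}_prom", "antibody": antibody,
            "Ct_input": float(ct_input), "Ct_sample": float(ct_sample),
            "Ct_mock": float(ct_mock), "mock_kind": mock_kind,
            "efficiency": E,
        })
        truth.locus_truth[(gene, antibody)] = float(pct)
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# developmental time course
# ---------------------------------------------------------------------------

def generate_timecourse(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Gene x stage expression levels with a gastrula burst subset.

    Baseline genes follow a slowly drifting log-normal level.  Burst genes
    jump by ``burst_fold`` at the designated gastrula transition and keep
    at least the pre-jump high level (small jitter aside) afterwards.
    Returns (levels, stage metadata, truth).
    """
    if len(config.stage_names) < 3:
        raise ConfigError("time course needs >= 3 stages")
    rng = _rng(config, "timecourse")
    genes = gene_ids(config.n_genes, prefix="g")
    n = config.n_genes
    stages = list(config.stage_names)
    gast_idx = stages.index(config.gastrula_transition[0])

    n_burst = int(round(config.burst_gene_fraction * n))
    burst = set(rng.choice(n, size=n_burst, replace=False).tolist())

    base = np.exp(rng.normal(config.mean_log_expression, 1.0, n))
    levels = np.empty((n, len(stages)))
    levels[:, 0] = base
    for s in range(1, len(stages)):
        drift = rng.normal(0.0, config.timecourse_noise_sd, n)
        levels[:, s] = levels[:, s - 1] * np.exp(drift)
        if s == gast_idx + 1 and n_burst:
            idx = np.fromiter(burst, dtype=int)
            levels[idx, s] = levels[idx, s - 1] * config.burst_fold
    # persistence: burst genes never fall below 50% of their peak later on
    if n_burst:
        idx = np.fromiter(burst, dtype=int)
        for s in range(gast_idx + 2, len(stages)):
            floor_lvl = 0.5 * levels[idx, gast_idx + 1]
            levels[idx, s] = np.maximum(levels[idx, s], floor_lvl)

    tc = pd.DataFrame(levels, index=pd.Index(genes, name="gene"), columns=stages)
    meta = pd.DataFrame({
        "stage": stages[:-1],
        "next_stage": stages[1:],
        "duration_h": list(config.stage_durations_h),
    })
    truth = GroundTruth(
        burst_genes={genes[i] for i in burst},
        library_scale=config.library_scale,
    )
    return tc, meta, truth


# ---------------------------------------------------------------------------
# cross-species ortholog epigenetic states
# ---------------------------------------------------------------------------

def _k27_prob_promoted(p0: float, odds_ratio: float) -> float:
    odds0 = p0 / (1.0 - p0)
    odds1 = odds0 * odds_ratio
    return odds1 / (1.0 + odds1)


def generate_ortholog_states(
    config: SimConfig,
    species: tuple[str, str] = ("mESC", "zebrafish"),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-gene, per-species H3K4me3/H3K27me3 flags plus promotion truth.

    Promoted genes carry H3K27me3 with probability p1 such that the odds
    ratio of (K27 vs not) x (promoted vs not) equals ``k27_odds_ratio`` in
    expectation, against a baseline probability ``k27_baseline_prob`` for
    control genes.  The second species reproduces the first species' state
    with probability ``conservation_prob`` and is redrawn from the
    marginal otherwise.
    """
    rng = _rng(config, "ortholog")
    n_pro, n_ctl = config.n_promoted_genes, config.n_control_genes
    genes = gene_ids(n_pro + n_ctl, prefix="g")
    promoted = [True] * n_pro + [False] * n_ctl
    p0 = config.k27_baseline_prob
    p1 = _k27_prob_promoted(p0, config.k27_odds_ratio)

    rows = []
    truth = GroundTruth(library_scale=config.library_scale)

    def draw_state(k27_p: float) -> tuple[bool, bool]:
        k27 = bool(rng.random() < k27_p)
        if k27:
            k4 = bool(rng.random() < 0.8)  # bivalent loci usually keep K4
        else:
            k4 = bool(rng.random() < config.k4_given_not_k27)
        return k4, k27

    for gene, is_pro in zip(genes, promoted):
        p_k27 = p1 if is_pro else p0
        k4_a, k27_a = draw_state(p_k27)
        if rng.random() < config.conservation_prob:
            k4_b, k27_b = k4_a, k27_a
        else:
            k4_b, k27_b = draw_state(p_k27)
        rows.append({"gene_id": gene, "species": species[0], "k4": k4_a, "k27": k27_a})
        rows.append({"gene_id": gene, "species": species[1], "k4": k4_b, "k27": k27_b})
        truth.gene_k27_state[gene] = k27_a or k27_b
        truth.gene_promoted[gene] = is_pro
    return pd.DataFrame(rows), truth
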