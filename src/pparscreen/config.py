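"""Simulation and pipeline configuration.

``SimConfig`` bundles every tunable of the synthetic-data generators: the
count model for the knock-down RNA-seq experiment (control "Co" versus
PPARβ-morpholino "MO" libraries), the qPCR amplification-curve model, the
ChIP-qPCR Ct model, the developmental time course, and the cross-species
epigenetic-state tables.  Defaults emulate the statistical structure of a
whole-embryo Xenopus laevis knock-down experiment at a toy scale of a few
thousand genes.

``PipelineConfig`` collects the analysis-stage parameters; every default
equals the value used in the study this package reanalyses (tag-pair
mapping: ≤5 N per pair, ≤1 mismatch per tag, ≤500 nt separation; gene-set
construction: top 200 most downregulated; ChIP positivity: percent input
>1% and enrichment over mock >5; developmental fold thresholds 2/4/8).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError

#: Xenopus laevis Nieuwkoop–Faber stages used by the synthetic time course.
#: One consecutive transition (stage 11 -> stage 13, spanning gastrulation)
#: is designated as the "gastrula" transition where burst genes switch on.
DEFAULT_STAGES = ("st9", "st10", "st11", "st13", "st15", "st20")
#: Hours between consecutive stages at standard rearing temperature.
DEFAULT_STAGE_DURATIONS_H = (2.0, 2.75, 3.0, 3.5, 7.0)
DEFAULT_GASTRULA_TRANSITION = ("st11", "st13")

DEFAULT_EFFICIENCIES = {
    "eef1a": 1.90,
    "rpl8": 1.95,
    "hoxa7": 1.80,
    "sox8": 1.85,
    "cdx4": 2.00,
}


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for every synthetic dataset.

    Counts: per-gene control means are log-normal
    (``mean_log_expression``/``sd_log_expression`` on the natural-log
    scale) and observed counts are negative-binomial with dispersion
    ``nb_dispersion`` (variance = m + dispersion * m**2).  MO counts get a
    global ``library_scale`` factor plus per-gene injected folds for the
    affected subsets.

    qPCR: fluorescence follows baseline + u/(1 + u/fmax) with
    u = F0 * E**cycle, plus Gaussian noise of sd ``curve_noise_sd``
    (absolute units; the default is 0.5% of ``fmax``).

    ChIP: sample Cts are generated by exactly inverting the percent-input
    formula P = E**(Ct_input - Ct_sample) * 100, so the formula is
    recoverable by construction.
    """

    seed: int = 0
    # --- count experiment -------------------------------------------------
    n_genes: int = 2000
    n_affected_down: int = 100
    n_affected_up: int = 50
    effect_fold_range: tuple[float, float] = (2.0, 8.0)
    library_scale: float = 0.8
    nb_dispersion: float = 0.1
    mean_log_expression: float = 4.595  # ln(99): the study's median tag count
    sd_log_expression: float = 1.8
    # --- transcriptome / tags ---------------------------------------------
    transcript_length: int = 1000
    tag_length: int = 25
    # --- developmental time course ----------------------------------------
    stage_names: tuple[str, ...] = DEFAULT_STAGES
    stage_durations_h: tuple[float, ...] = DEFAULT_STAGE_DURATIONS_H
    gastrula_transition: tuple[str, str] = DEFAULT_GASTRULA_TRANSITION
    burst_gene_fraction: float = 0.05
    burst_fold: float = 8.0
    timecourse_noise_sd: float = 0.05  # sd of log-level jitter per stage
    # --- qPCR amplification curves ----------------------------------------
    true_efficiencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFICIENCIES)
    )
    fmax: float = 1.0
    curve_noise_sd: float = 0.005
    curve_baseline: float = 0.05
    n_cycles: int = 40
    # --- ChIP-qPCR ---------------------------------------------------------
    input_ct_mean: float = 25.0
    true_percent_input: Mapping[tuple[str, str], float] = field(default_factory=dict)
    mock_percent_input: float = 0.1
    chip_ct_noise_sd: float = 0.0
    chip_efficiency: float = 2.0
    # --- ortholog epigenetic states ----------------------------------------
    k27_odds_ratio: float = 17.33
    k27_baseline_prob: float = 1.0 / 27.0
    k4_given_not_k27: float = 0.7
    conservation_prob: float = 0.8
    n_promoted_genes: int = 35
    n_control_genes: int = 27

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_affected_down < 0 or self.n_affected_up < 0:
            raise ConfigError("affected-gene counts must be non-negative")
        if self.n_affected_down + self.n_affected_up > self.n_genes:
            raise ConfigError(
                "n_affected_down + n_affected_up exceeds n_genes "
                f"({self.n_affected_down}+{self.n_affected_up} > {self.n_genes})"
            )
        lo, hi = self.effect_fold_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ConfigError("effect_fold_range must be positive and ordered")
        if self.library_scale <= 0:
            raise ConfigError("library_scale must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        for primer, eff in self.true_efficiencies.items():
            if not 1.0 < eff <= 2.0:
                raise ConfigError(
                    f"efficiency for {primer!r} must be in (1, 2], got {eff}"
                )
        if not 1.0 < self.chip_efficiency <= 2.0:
            raise ConfigError("chip_efficiency must be in (1, 2]")
        if len(self.stage_durations_h) != len(self.stage_names) - 1:
            raise ConfigError(
                "stage_durations_h must have one entry per consecutive stage pair"
            )
        if any(d <= 0 for d in self.stage_durations_h):
            raise ConfigError("stage durations must be positive")
        if not 0.0 <= self.burst_gene_fraction <= 1.0:
            raise ConfigError("burst_gene_fraction must be in [0, 1]")
        if self.burst_fold < 4.0:
            raise ConfigError("burst_fold must be >= 4")
        if self.curve_noise_sd < 0:
            raise ConfigError("curve_noise_sd must be >= 0")
        if self.fmax <= 0:
            raise ConfigError("fmax must be > 0")
        if self.mock_percent_input <= 0:
            raise ConfigError("mock_percent_input must be > 0")
        for key, pct in self.true_percent_input.items():
            if pct <= 0:
                raise ConfigError(f"true_percent_input for {key!r} must be > 0")
        if self.k27_odds_ratio <= 0:
            raise ConfigError("k27_odds_ratio must be > 0")
        if not 0.0 <= self.conservation_prob <= 1.0:
            raise ConfigError("conservation_prob must be in [0, 1]")
        if not 0.0 < self.k27_baseline_prob < 1.0:
            raise ConfigError("k27_baseline_prob must be in (0, 1)")
        if self.transcript_length < 2 * self.tag_length + 10:
            raise ConfigError(
                "transcript_length must be >= 2 * tag_length + 10"
            )
        gast_from, gast_to = self.gastrula_transition
        names = list(self.stage_names)
        if gast_from not in names or gast_to not in names:
            raise ConfigError("gastrula_transition stages must be in stage_names")
        if names.index(gast_to) != names.index(gast_from) + 1:
            raise ConfigError("gastrula_transition must be a consecutive stage pair")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-stage parameters with the study's published defaults."""

    seed: int = 0
    # tag mapping
    max_n_per_pair: int = 5
    max_mismatch: int = 1
    max_separation: int = 500
    # normalization / ranking
    scale_factor: float | None = None  # None -> median-ratio estimate
    pseudocount: float = 0.5
    unchanged_band: tuple[float, float] = (0.9, 1.1)
    top_n: int = 200
    # qPCR
    qpcr_window: int = 5
    qpcr_min_r2: float = 0.99
    reference_genes: tuple[str, ...] = ("eef1a", "rpl8")
    # ChIP scoring
    input_min: float = 1.0
    enr_min: float = 5.0
    # developmental dynamics
    fold_thresholds: tuple[float, ...] = (2.0, 4.0, 8.0)
    burst_min_fold: float = 4.0
    # Fisher test
    fisher_sided: str = "two"

    def __post_init__(self) -> None:
        if self.max_n_per_pair < 0 or self.max_mismatch < 0:
            raise ConfigError("mapping filter parameters must be non-negative")
        if self.max_separation < 1:
            raise ConfigError("max_separation must be >= 1")
        if self.scale_factor is not None and self.scale_factor <= 0:
            raise ConfigError("scale_factor override must be > 0")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        lo, hi = self.unchanged_band
        if not lo < 1.0 < hi:
            raise ConfigError("unchanged_band must contain 1")
        if self.qpcr_window < 3:
            raise ConfigError("qpcr_window must be >= 3")
        if not 0.0 < self.qpcr_min_r2 <= 1.0:
            raise ConfigError("qpcr_min_r2 must be in (0, 1]")
        if any(t <= 1 for t in self.fold_thresholds):
            raise ConfigError("fold thresholds must exceed 1")
        if self.fisher_sided not in ("two", "greater"):
            raise ConfigError("fisher_sided must be 'two' or 'greater'")


def _coerce(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = dict(data)
    for key in ("effect_fold_range", "stage_names", "stage_durations_h",
                "gastrula_transition", "unchanged_band", "fold_thresholds",
                "reference_genes"):
        if key in coerced and isinstance(coerced[key], list):
            coerced[key] = tuple(coerced[key])
    if "true_percent_input" in coerced and isinstance(coerced["true_percent_input"], dict):
        coerced["true_percent_input"] = {
            tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
            for k, v in coerced["true_percent_input"].items()
        }
    return cls(**coerced)


def load_sim_config(path) -> SimConfig:
    """Read a SimConfig from a YAML file (top-level key ``simulate`` optional)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _coerce(SimConfig, data.get("simulate", data))


def load_pipeline_config(path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML file (key ``pipeline`` optional)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _coerce(PipelineConfig, data.get("pipeline", data))
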