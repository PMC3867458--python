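"""End-to-end orchestration of the analysis stages on one dataset suite.

``run_all`` executes: simulate -> map-tags -> normalize/rank -> qpcr ->
chip-score -> classify -> enrich-test -> dev-rates, writing each stage's
tables under the output directory and a run manifest (config snapshot,
input checksums, per-stage record counts, timestamps) as JSON.  Re-running
with an identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import sys
import time
from pathlib import Path

import pandas as pd

from . import chip, devdyn, epiclass, normalize, qpcr, simulate, tagmap
from .config import PipelineConfig, SimConfig
from .errors import PparscreenError
from .io import read_gene_set, write_fasta, write_gene_set, write_json, write_tsv

STAGES = ("simulate", "map_tags", "normalize_rank", "qpcr", "chip_score",
          "classify", "enrich_test", "dev_rates")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(stage: str, message: str, verbose: bool = True) -> None:
    if verbose:
        print(f"[{stage}] {message}", file=sys.stderr)


def chip_config_from_states(sim: SimConfig, k27_state: dict[str, bool],
                            positive_pct: float = 5.0,
                            negative_pct: float = 0.3) -> SimConfig:
    """Generation-side helper: a SimConfig whose ChIP truth realizes
    the given per-gene H3K27me3 states (part of data synthesis, not of
    the analysis)."""
    truth = {(g, "H3K27me3"): (positive_pct if state else negative_pct)
             for g, state in k27_state.items()}
    return dataclasses.replace(sim, true_percent_input=truth)


def run_all(
    outdir,
    sim: SimConfig | None = None,
    params: PipelineConfig | None = None,
    n_mapping_transcripts: int = 30,
    verbose: bool = True,
) -> dict:
    """Run every stage on a self-generated dataset suite; return the manifest."""
    sim = sim if sim is not None else SimConfig()
    params = params if params is not None else PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "simulate": _jsonable_config(sim),
            "pipeline": _jsonable_config(params),
        },
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage: str, counts: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "records": counts,
            "checksums": {f.name: _sha256(f) for f in files},
        }
        _log(stage, f"done: {counts}", verbose)

    # --- simulate ---------------------------------------------------------
    map_sim = dataclasses.replace(sim, n_genes=n_mapping_transcripts,
                                  n_affected_down=0, n_affected_up=0)
    transcripts = simulate.generate_transcriptome(map_sim)
    pairs = simulate.generate_tag_pairs(
        transcripts, n_pairs_per_transcript=3, mismatch_rate=0.005,
        n_rate=0.002, decoy_fraction=0.05, seed=sim.seed,
        tag_length=sim.tag_length)
    counts, count_truth = simulate.generate_count_experiment(sim)
    curves, curve_truth = simulate.generate_amplification_curves(sim)
    tc, stage_meta, tc_truth = simulate.generate_timecourse(sim)
    states, state_truth = simulate.generate_ortholog_states(sim)
    chip_sim = chip_config_from_states(sim, state_truth.gene_k27_state)
    chip_meas, chip_truth = simulate.generate_chip_experiment(chip_sim)
    # the screened gene lists are part of the experimental design and are
    # emitted as dataset files; downstream stages read these, never the truth
    screen_promoted = [g for g, p in state_truth.gene_promoted.items() if p]
    screen_control = [g for g, p in state_truth.gene_promoted.items() if not p]

    fa = out / "transcripts.fasta"
    write_fasta(transcripts, fa)
    files = [fa]
    for name, df in [("tag_pairs.tsv", pairs), ("counts.tsv", counts.reset_index()),
                     ("curves.tsv", curves), ("timecourse.tsv", tc.reset_index()),
                     ("stage_meta.tsv", stage_meta),
                     ("epi_states.tsv", states), ("chip_cts.tsv", chip_meas)]:
        write_tsv(df, out / name)
        files.append(out / name)
    write_gene_set(screen_promoted, out / "screen_promoted.txt")
    write_gene_set(screen_control, out / "screen_control.txt")
    files += [out / "screen_promoted.txt", out / "screen_control.txt"]
    truth_path = out / "ground_truth.json"
    write_json({
        "counts": count_truth.to_jsonable(),
        "timecourse": tc_truth.to_jsonable(),
        "ortholog": state_truth.to_jsonable(),
        "chip": chip_truth.to_jsonable(),
    }, truth_path)
    files.append(truth_path)
    record("simulate", {"transcripts": len(transcripts), "pairs": len(pairs),
                        "genes": len(counts), "curves": int(curves["well_id"].nunique()),
                        "chip_loci": len(chip_meas)}, files)

    # --- map-tags ---------------------------------------------------------
    hits, rejections = tagmap.map_pairs(
        pairs[["pair_id", "tag1", "tag2"]], transcripts,
        max_mismatch=params.max_mismatch,
        max_separation=params.max_separation, max_n=params.max_n_per_pair)
    hits_df = tagmap.hits_frame(hits)
    rej_df = tagmap.rejections_frame(rejections)
    tag_counts = tagmap.count_tags(hits, transcripts)
    write_tsv(hits_df, out / "tag_hits.tsv")
    write_tsv(rej_df, out / "tag_rejections.tsv")
    write_tsv(tag_counts.rename("count").reset_index(), out / "tag_counts.tsv")
    record("map_tags", {"valid": len(hits_df), "rejected": len(rej_df)},
           [out / "tag_hits.tsv", out / "tag_rejections.tsv", out / "tag_counts.tsv"])

    # --- normalize / rank -------------------------------------------------
    norm = normalize.normalize(counts, scale_factor=params.scale_factor)
    reg = normalize.relative_abundance(norm, pseudocount=params.pseudocount)
    promoted, control = normalize.select_gene_sets(
        reg, top_n=params.top_n, unchanged_band=params.unchanged_band)
    write_tsv(norm.adjusted.reset_index(), out / "counts_adjusted.tsv")
    write_tsv(reg.reset_index(), out / "regulation.tsv")
    write_gene_set(promoted, out / "promoted_candidates.txt")
    write_gene_set(control, out / "control_candidates.txt")
    write_json({"scale_factor": norm.scale_factor,
                "summary": norm.summary_dict()}, out / "normalization.json")
    record("normalize_rank",
           {"genes": len(reg), "promoted": len(promoted), "control": len(control)},
           [out / "counts_adjusted.tsv", out / "regulation.tsv",
            out / "normalization.json"])

    # --- qpcr -------------------------------------------------------------
    eff = qpcr.estimate_all_efficiencies(curves, window=params.qpcr_window,
                                         min_r2=params.qpcr_min_r2)
    write_tsv(eff, out / "efficiencies.tsv")
    ct_rows = []
    thr = 0.1 * sim.fmax
    for well, grp in curves.groupby("well_id"):
        grp = grp.sort_values("cycle")
        ct = qpcr.call_ct(grp["cycle"], grp["fluorescence"], thr)
        ct_rows.append({"gene_id": grp["primer_id"].iloc[0],
                        "sample_id": grp["sample_id"].iloc[0],
                        "Ct": ct})
    ct_table = pd.DataFrame(ct_rows)
    rq = qpcr.relative_quantities(ct_table, eff)
    normed = qpcr.normalize_to_references(rq, params.reference_genes)
    folds = qpcr.fold_mo_vs_co(normed)
    write_tsv(rq, out / "relative_quantities.tsv")
    write_tsv(normed, out / "normalized_quantities.tsv")
    write_tsv(folds, out / "qpcr_folds.tsv")
    record("qpcr", {"primers": len(eff), "cts": len(ct_table),
                    "genes_folded": len(folds)},
           [out / "efficiencies.tsv", out / "relative_quantities.tsv",
            out / "normalized_quantities.tsv", out / "qpcr_folds.tsv"])

    # --- chip-score (reads the emitted screen design files) ---------------
    promoted_chip = read_gene_set(out / "screen_promoted.txt")
    control_chip = read_gene_set(out / "screen_control.txt")
    calls, screen_summary = chip.screen_gene_sets(
        chip_meas, promoted_chip, control_chip,
        input_min=params.input_min, enr_min=params.enr_min)
    write_tsv(calls, out / "mark_calls.tsv")
    write_json(screen_summary, out / "screen_summary.json")
    record("chip_score", screen_summary,
           [out / "mark_calls.tsv", out / "screen_summary.json"])

    # --- classify ---------------------------------------------------------
    classes = epiclass.classify_table(states)
    write_tsv(classes, out / "gene_classes.tsv")
    record("classify",
           {"genes": len(classes),
            "k27": int((classes["gene_class"] == "K27").sum()),
            "conserved": int(classes["conserved"].sum())},
           [out / "gene_classes.tsv"])

    # --- enrich-test ------------------------------------------------------
    positives = set(calls.loc[calls["positive"], "gene_id"])
    table = epiclass.build_contingency(promoted_chip, control_chip, positives)
    result = epiclass.fisher_exact(table)
    fisher_report = {
        "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "p_two_sided": result.p_two_sided,
        "p_one_sided_greater": result.p_one_sided_greater,
        "odds_ratio": (None if result.odds_ratio != result.odds_ratio
                       else result.odds_ratio),
    }
    write_json(fisher_report, out / "fisher.json")
    record("enrich_test", {"a": table.a, "b": table.b, "c": table.c,
                           "d": table.d}, [out / "fisher.json"])

    # --- dev-rates --------------------------------------------------------
    rates = devdyn.transition_rates(tc, stage_meta["duration_h"],
                                    thresholds=params.fold_thresholds)
    burst = devdyn.burst_set(tc, sim.gastrula_transition[0],
                             sim.gastrula_transition[1],
                             min_fold=params.burst_min_fold)
    profile = devdyn.persistence_profile(tc, burst) if burst else pd.DataFrame()
    write_tsv(rates, out / "transition_rates.tsv")
    write_gene_set(burst, out / "burst_genes.txt")
    if not profile.empty:
        write_tsv(profile, out / "persistence_profile.tsv")
    record("dev_rates", {"transitions": int(len(stage_meta)),
                         "burst_genes": len(burst)},
           [out / "transition_rates.tsv"])

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    write_json(manifest, out / "manifest.json")
    return manifest


def _jsonable_config(cfg) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, dict):
            v = {"|".join(k) if isinstance(k, tuple) else k: val
                 for k, val in v.items()}
        out[f.name] = v
    return out
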