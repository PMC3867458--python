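# pparscreen

Analysis toolkit for a loss-of-function screen asking whether the nuclear
receptor PPARβ preferentially activates genes that carry the repressive
H3K27me3 chromatin mark at the onset of *Xenopus laevis* gastrulation.

The package is aimed at developmental epigenomics analysts who want the
complete, testable computational chain behind such a screen:

- **Tag mapping** — paired-end tags are placed on a transcript set with
  the screen's validity filters (≤ 5 `N` per pair, ≤ 1 mismatch per tag,
  same unique mRNA, convergent mates ≤ 500 nt apart) and counted per mRNA.
- **Count normalization** — the morpholino (MO) library is scaled onto the
  control (Co) distribution by a median ratio under the
  most-genes-unaffected assumption; genes are ranked by fold
  `(MO + c)/(Co + c)` and the top-200 most downregulated become
  PPARβ-promoted candidates.
- **qPCR quantification** — amplification efficiency `E` per primer is
  estimated from the curves' window of linearity (`E = 10^slope`), and
  relative quantities `RQ = E^(Ct_cal − Ct)` are normalized to the EEF1a
  and RPL8 reference genes.
- **ChIP-qPCR scoring** — percent input
  `P = E^(Ct_input − Ct_sample) × 100`, enrichment = P(IP)/P(mock), and a
  locus is mark-positive iff P > 1 % **and** enrichment > 5 (both strict).
- **Developmental dynamics** — per-stage-transition counts of genes
  changing ≥ 2×/4×/8×, normalized by transition duration in hours, and
  persistence percentile envelopes of the gastrula-burst gene set.
- **Enrichment testing** — an exact Fisher test (implemented from
  hypergeometric point probabilities) of the 2×2 table: gene-set
  membership (promoted vs control) × H3K27me3 positivity.
- **Synthetic data** — generators for every input with injected ground
  truth (fold effects, library scale, efficiencies, percent inputs, burst
  genes, a tunable K27×promotion odds ratio), so each stage's recovery is
  measurable without any download.

## Worked example

Run the whole pipeline on a self-generated dataset suite:

```sh
pparscreen run-all --seed 5 --outdir out/
```

which prints, stage by stage:

```
[simulate] done: {'transcripts': 30, 'pairs': 90, 'genes': 2000, 'curves': 40, 'chip_loci': 62}
[map_tags] done: {'valid': 81, 'rejected': 9}
[normalize_rank] done: {'genes': 2000, 'promoted': 200, 'control': 297}
[qpcr] done: {'primers': 5, 'cts': 40, 'genes_folded': 5}
[chip_score] done: {'promoted_positive': 19, 'promoted_total': 35, 'control_positive': 1, 'control_total': 27}
[classify] done: {'genes': 62, 'k27': 20, 'conserved': 44}
[enrich_test] done: {'a': 19, 'b': 16, 'c': 1, 'd': 26}
[dev_rates] done: {'transitions': 5, 'burst_genes': 100}
completed 8 stages
```

Reading the output: of 90 simulated tag pairs, 81 pass all mapping
filters; the 2 000-gene count table yields 200 promoted and 297 unchanged
control candidates; 5 primers are quantified across 40 wells; in the
simulated ChIP screen 19 of 35 promoted genes but only 1 of 27 controls
score H3K27me3-positive, giving the contingency table (19, 16, 1, 26)
whose Fisher p (in `out/fisher.json`, here 1.9e-05) rejects independence —
the simulated analogue of the screen's conclusion that PPARβ-promoted
genes are enriched for the K27 mark. `out/manifest.json` records the
config snapshot, per-stage record counts and output checksums; identical
configs reproduce byte-identical outputs.

The same stages are available individually (`simulate`, `map-tags`,
`normalize`, `rank`, `qpcr-efficiency`, `qpcr-quant`, `chip-score`,
`classify`, `enrich-test`, `dev-rates`, `dev-persistence`), e.g.:

```sh
pparscreen enrich-test --promoted promoted.txt --control control.txt \
    --calls mark_calls.tsv --sided two --out fisher.json
# Fisher exact p (two-sided) = 1.86e-05
```

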