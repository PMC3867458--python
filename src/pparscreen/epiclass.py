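"""Epigenetic-state classification and Fisher exact enrichment testing.

Genes are classed from the H3K4me3/H3K27me3 flags of their orthologs in
pluripotent cells: 'K27' when H3K27me3 is present regardless of H3K4me3
co-occupancy, 'K4_only' when only H3K4me3 is present, 'unmarked' when
neither is.  A class is conserved when both species (mouse ESC and
zebrafish blastula) yield the same K27 or K4-only call.  The association
between K27 status and PPARβ-dependent promotion is tested with an exact
hypergeometric (Fisher) test implemented here from log-gamma point
probabilities; the two-sided p sums all tables with the observed margins
whose point probability does not exceed the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import IntegrityError, InvalidInputError

CLASSES = ("K27", "K4_only", "unmarked")


def classify_gene(k4: bool, k27: bool) -> str:
    """'K27' dominates: the mark counts regardless of H3K4me3 co-occupancy."""
    if k27:
        return "K27"
    if k4:
        return "K4_only"
    return "unmarked"


@dataclass(frozen=True)
class GeneClass:
    gene_id: str
    gene_class: str  # K27 / K4_only / unmarked / unclassified
    conserved: bool
    per_species: dict


def conserved_class(table: pd.DataFrame, gene: str) -> GeneClass:
    """Class of one gene with its cross-species conservation status.

    Conserved requires both species present and agreeing on K27 or
    K4_only.  With a single species the class is retained, unconserved.
    A gene absent from the table is 'unclassified' (distinct from
    'unmarked': no measurement, not a double-negative one).
    """
    rows = table[table["gene_id"] == gene]
    if rows.empty:
        return GeneClass(gene, "unclassified", False, {})
    per_species = {
        r["species"]: classify_gene(bool(r["k4"]), bool(r["k27"]))
        for _, r in rows.iterrows()
    }
    classes = list(per_species.values())
    if len(per_species) >= 2 and len(set(classes)) == 1 and classes[0] in ("K27", "K4_only"):
        return GeneClass(gene, classes[0], True, per_species)
    # single species, or disagreement: keep a deterministic primary class
    # (K27 wherever any species shows it, else K4_only, else unmarked)
    if "K27" in classes:
        primary = "K27"
    elif "K4_only" in classes:
        primary = "K4_only"
    else:
        primary = "unmarked"
    return GeneClass(gene, primary, False, per_species)


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """GeneClass rows for every gene in an epi-state table."""
    dup = table.duplicated(subset=["gene_id", "species"])
    if dup.any():
        raise IntegrityError("duplicate (gene, species) rows in state table")
    rows = []
    for gene in pd.unique(table["gene_id"]):
        gc = conserved_class(table, gene)
        rows.append({"gene_id": gc.gene_id, "gene_class": gc.gene_class,
                     "conserved": gc.conserved})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: gene-set membership; columns: mark positive / negative."""

    a: int  # promoted & positive
    b: int  # promoted & negative
    c: int  # control & positive
    d: int  # control & negative

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidInputError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingency(promoted_genes, control_genes, mark_positive) -> ContingencyTable2x2:
    """Cross-tabulate set membership against mark positivity.

    ``mark_positive`` is a mapping gene -> bool (or a set of positive
    genes); every gene of both sets must be covered.
    """
    promoted, control = set(promoted_genes), set(control_genes)
    overlap = promoted & control
    if overlap:
        raise IntegrityError(f"genes in both sets: {sorted(overlap)[:5]}")
    if isinstance(mark_positive, (set, frozenset)):
        lookup = {g: (g in mark_positive) for g in promoted | control}
    else:
        missing = (promoted | control) - set(mark_positive)
        if missing:
            raise IntegrityError(f"no mark call for genes: {sorted(missing)[:5]}")
        lookup = dict(mark_positive)
    a = sum(1 for g in promoted if lookup[g])
    c = sum(1 for g in control if lookup[g])
    return ContingencyTable2x2(a, len(promoted) - a, c, len(control) - c)


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    p_one_sided_greater: float
    odds_ratio: float
    degenerate: bool = False


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact(t: ContingencyTable2x2) -> FisherResult:
    """Exact hypergeometric test on a 2x2 table.

    Two-sided p: sum of hypergeometric probabilities of every table with
    the observed margins whose point probability is at most the observed
    table's (within a 1e-12 relative tolerance).  One-sided greater: upper
    tail on cell a.  Odds ratio: a*d / (b*c), infinite when b*c = 0.
    A degenerate margin (empty row or column) gives p = 1, flagged.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.total
    if n < 1:
        raise InvalidInputError("empty contingency table")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        odds = _odds_ratio(a, b, c, d)
        return FisherResult(1.0, 1.0, odds, degenerate=True)

    lo, hi = max(0, r1 - c2), min(r1, c1)
    log_norm = _log_binom(n, c1)

    def log_prob(k: int) -> float:
        return _log_binom(r1, k) + _log_binom(r2, c1 - k) - log_norm

    lp_obs = log_prob(a)
    p_two = 0.0
    p_greater = 0.0
    for k in range(lo, hi + 1):
        lp = log_prob(k)
        if lp <= lp_obs + 1e-12:
            p_two += math.exp(lp)
        if k >= a:
            p_greater += math.exp(lp)
    return FisherResult(min(p_two, 1.0), min(p_greater, 1.0),
                        _odds_ratio(a, b, c, d))


def _odds_ratio(a, b, c, d) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def overlap_summary(set_a, set_b, set_c,
                    labels=("promoted", "k27", "burst"),
                    universe=None) -> dict:
    """Counts for every region of the three-set partition plus totals.

    The outside region is only countable against an explicit ``universe``;
    without one it is reported as 0.
    """
    A, B, C = set(set_a), set(set_b), set(set_c)
    la, lb, lc = labels
    outside = len(set(universe) - A - B - C) if universe is not None else 0
    return {
        f"{la}_only": len(A - B - C),
        f"{lb}_only": len(B - A - C),
        f"{lc}_only": len(C - A - B),
        f"{la}_{lb}": len((A & B) - C),
        f"{la}_{lc}": len((A & C) - B),
        f"{lb}_{lc}": len((B & C) - A),
        f"{la}_{lb}_{lc}": len(A & B & C),
        "none": outside,
        "totals": {la: len(A), lb: len(B), lc: len(C)},
    }
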