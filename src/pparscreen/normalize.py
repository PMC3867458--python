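"""Count normalization, fold ranking and gene-set construction.

The two libraries (control morpholino "Co" and PPARβ morpholino "MO") are
put on a common scale under the assumption that most genes are unaffected
by the knock-down: the MO column is multiplied by the ratio of the two
medians over co-detected genes, which equalizes the medians exactly.  The
original analysis used the same distribution-matching idea and reported
the factor 0.799; that value can be supplied as an override to reproduce
the published adjusted summaries.

Downregulation rank 1 = the gene most reduced by the knock-down, i.e. the
strongest candidate for a PPARβ-promoted transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError, InvalidInputError

FIVE_NUMBER_LABELS = ("lowest", "q1", "median", "q3", "maximum")


def count_summary(column) -> tuple[float, float, float, float, float]:
    """Five-number summary (lowest, Q1, median, Q3, maximum).

    Quartiles use linear interpolation between order statistics.
    """
    arr = np.asarray(column, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("empty count column")
    q = np.percentile(arr, [0, 25, 50, 75, 100], method="linear")
    return tuple(float(x) for x in q)


@dataclass(frozen=True)
class NormalizationResult:
    scale_factor: float
    adjusted: pd.DataFrame  # columns Co (raw) and MO (scaled)
    summary: pd.DataFrame  # five-number summaries per condition

    def summary_dict(self) -> dict:
        return {cond: dict(zip(FIVE_NUMBER_LABELS, row))
                for cond, row in self.summary.iterrows()}


def distribution_scale_factor(table: pd.DataFrame) -> float:
    """Median-ratio factor putting MO on the Co scale.

    Computed over genes detected in at least one condition; multiplying
    the MO column by the result equalizes the two medians.
    """
    _check_table(table)
    detected = table[(table["Co"] + table["MO"]) > 0]
    med_co = float(np.median(detected["Co"]))
    med_mo = float(np.median(detected["MO"]))
    if med_mo == 0 or med_co == 0:
        raise DegenerateInputError("median of a condition is zero")
    return med_co / med_mo


def apply_scale(table: pd.DataFrame, factor: float) -> NormalizationResult:
    """Scale the MO column; Co is left untouched.

    Five-number summaries are computed over genes detected in at least one
    condition (the same subset the scale factor is estimated on), so the
    median-ratio factor equalizes the reported medians exactly.
    """
    _check_table(table)
    if factor <= 0:
        raise InvalidInputError(f"scale factor must be > 0, got {factor}")
    adjusted = table.copy()
    adjusted["MO"] = adjusted["MO"] * factor
    detected = adjusted[(adjusted["Co"] + adjusted["MO"]) > 0]
    summary = pd.DataFrame(
        [count_summary(detected["Co"]), count_summary(detected["MO"])],
        index=pd.Index(["Co", "MO"], name="condition"),
        columns=list(FIVE_NUMBER_LABELS),
    )
    return NormalizationResult(scale_factor=factor, adjusted=adjusted,
                               summary=summary)


def normalize(table: pd.DataFrame, scale_factor: float | None = None) -> NormalizationResult:
    """Estimate (or accept) the scale factor and apply it."""
    factor = distribution_scale_factor(table) if scale_factor is None else scale_factor
    return apply_scale(table, factor)


def relative_abundance(norm: NormalizationResult, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene fold (adjusted MO / Co) and downregulation rank.

    fold = (adjMO + pseudocount) / (Co + pseudocount).  Rank 1 is the most
    downregulated gene; ties are broken by higher Co count (better
    detected first) then lexicographic gene id.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    adj = norm.adjusted
    reg = pd.DataFrame({
        "Co": adj["Co"],
        "adjMO": adj["MO"],
        "fold": (adj["MO"] + pseudocount) / (adj["Co"] + pseudocount),
    })
    order = reg.assign(_id=reg.index.astype(str)).sort_values(
        ["fold", "Co", "_id"], ascending=[True, False, True], kind="mergesort")
    reg["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return reg


def select_gene_sets(
    reg: pd.DataFrame,
    top_n: int = 200,
    unchanged_band: tuple[float, float] = (0.9, 1.1),
) -> tuple[list[str], list[str]]:
    """Promoted candidates (top downregulated) and unchanged controls.

    A gene the MO reduces is a gene PPARβ promotes, so the ``top_n`` most
    downregulated genes are the promoted candidates.  Controls are genes
    whose fold sits inside ``unchanged_band``; candidates already in the
    promoted set are excluded so the sets are disjoint.
    """
    lo, hi = unchanged_band
    if not lo < 1.0 < hi:
        raise ConfigError("unchanged_band must contain 1")
    if top_n > len(reg):
        raise ConfigError(f"top_n={top_n} exceeds gene count {len(reg)}")
    promoted = reg.index[reg["rank"] <= top_n].tolist()
    in_band = reg[(reg["fold"] >= lo) & (reg["fold"] <= hi)]
    control = [g for g in in_band.index if g not in set(promoted)]
    return promoted, control


def _check_table(table: pd.DataFrame) -> None:
    for cond in ("Co", "MO"):
        if cond not in table.columns:
            raise InvalidInputError(f"count table lacks condition {cond!r}")
        col = table[cond]
        if (col < 0).any():
            raise InvalidInputError(f"negative counts in {cond}")
        if not (col > 0).any():
            raise DegenerateInputError(f"all-zero count column {cond}")
    if table.index.duplicated().any():
        raise InvalidInputError("duplicate gene ids in count table")
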