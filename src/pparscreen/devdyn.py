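"""Developmental transcriptome dynamics across stage transitions.

Counts, for each consecutive pair of developmental stages, how many genes
change RNA level by at least 2x, 4x or 8x in either direction, normalized
by the duration in hours of the transition — the statistic showing that
transcriptome change peaks at gastrulation.  The genes induced 4x or more
over the gastrula transition (stage 11 -> 13) form the "burst" set whose
per-stage percentile envelope demonstrates that they keep their induced
level through later development.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidInputError

PERSISTENCE_PERCENTILES = (10, 25, 50, 75, 90)


def _fold_matrix(tc: pd.DataFrame, floor: float | None) -> tuple[pd.DataFrame, float]:
    levels = tc.to_numpy(dtype=float)
    if (levels < 0).any():
        raise InvalidInputError("negative expression levels")
    if floor is None:
        positive = levels[levels > 0]
        if positive.size == 0:
            raise DegenerateInputError("all levels are zero")
        floor = 0.5 * float(positive.min())
    if floor <= 0:
        raise InvalidInputError("floor must be > 0")
    return tc, floor


def transition_rates(
    tc: pd.DataFrame,
    durations_h,
    thresholds=(2.0, 4.0, 8.0),
    floor: float | None = None,
) -> pd.DataFrame:
    """Gene counts (and counts per hour) crossing each fold threshold.

    ``tc`` is gene x stage (ordered columns); ``durations_h`` gives the
    hours spanned by each consecutive stage pair.  A gene counts as an
    increase at threshold t over a transition iff
    level(next) / max(level(prev), floor) >= t, symmetrically for
    decreases (both levels floored), so the count columns are nested:
    count(8x) <= count(4x) <= count(2x).
    """
    if any(t <= 1 for t in thresholds):
        raise InvalidInputError("thresholds must exceed 1")
    stages = list(tc.columns)
    durations = list(durations_h)
    if len(durations) != len(stages) - 1:
        raise InvalidInputError("need one duration per consecutive stage pair")
    if any(d <= 0 for d in durations):
        raise InvalidInputError("durations must be positive")
    tc, floor = _fold_matrix(tc, floor)
    rows = []
    for i in range(len(stages) - 1):
        prev = np.maximum(tc[stages[i]].to_numpy(dtype=float), floor)
        nxt = np.maximum(tc[stages[i + 1]].to_numpy(dtype=float), floor)
        ratio = nxt / prev
        for t in thresholds:
            for direction, n in (("increase", int((ratio >= t).sum())),
                                 ("decrease", int((ratio <= 1.0 / t).sum()))):
                rows.append({
                    "from_stage": stages[i], "to_stage": stages[i + 1],
                    "threshold": float(t), "direction": direction,
                    "n_genes": n, "duration_h": float(durations[i]),
                    "genes_per_hour": n / float(durations[i]),
                })
    return pd.DataFrame(rows)


def burst_set(
    tc: pd.DataFrame,
    from_stage: str,
    to_stage: str,
    min_fold: float = 4.0,
    floor: float | None = None,
) -> list[str]:
    """Genes induced ``min_fold``x or more between two stages."""
    for stage in (from_stage, to_stage):
        if stage not in tc.columns:
            raise InvalidInputError(f"unknown stage {stage!r}")
    if list(tc.columns).index(from_stage) >= list(tc.columns).index(to_stage):
        raise InvalidInputError("from_stage must precede to_stage")
    if len(tc) == 0:
        return []
    tc, floor = _fold_matrix(tc, floor)
    prev = np.maximum(tc[from_stage].to_numpy(dtype=float), floor)
    ratio = tc[to_stage].to_numpy(dtype=float) / prev
    return tc.index[ratio >= min_fold].tolist()


def persistence_profile(tc: pd.DataFrame, gene_set) -> pd.DataFrame:
    """Per-stage 10/25/50/75/90th percentiles of levels over a gene set.

    The envelope behind the box-and-whisker view of whether gastrula-
    induced genes maintain their induced expression at later stages.
    """
    genes = list(gene_set)
    if not genes:
        raise InvalidInputError("empty gene set")
    missing = set(genes) - set(tc.index)
    if missing:
        raise InvalidInputError(f"genes not in time course: {sorted(missing)[:5]}")
    sub = tc.loc[genes]
    rows = []
    for stage in tc.columns:
        q = np.percentile(sub[stage].to_numpy(dtype=float),
                          PERSISTENCE_PERCENTILES, method="linear")
        rows.append({"stage": stage,
                     **{f"p{p}": float(v)
                        for p, v in zip(PERSISTENCE_PERCENTILES, q)}})
    return pd.DataFrame(rows)
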