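"""ChIP-qPCR scoring: percent input, enrichment over mock, mark calls.

Percent input expresses the immunoprecipitated signal as a fraction of
the pre-IP chromatin: P = E**(Ct_input - Ct_sample) * 100, with E the
gene-specific amplification efficiency.  Enrichment is the ratio of the
IP's percent input over the negative control's (empty beads for the
histone marks; the PPARβ-morpholino signal for the PPARβ antibody).  A
locus is scored positive for a mark when BOTH strict criteria hold:
percent input > 1% and enrichment over mock > 5.  A gene positive for
H3K4me3 and H3K27me3 at the same locus is called bivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import IntegrityError, InvalidInputError


def percent_input(efficiency: float, ct_input: float, ct_sample: float) -> float:
    """E**(Ct_input - Ct_sample) * 100."""
    if efficiency <= 1:
        raise InvalidInputError(f"efficiency must be > 1, got {efficiency}")
    return efficiency ** (ct_input - ct_sample) * 100.0


def enrichment(percent_input_ip: float, percent_input_mock: float) -> float:
    """Ratio of IP percent input over the negative control's."""
    if percent_input_mock <= 0:
        raise InvalidInputError("mock percent input must be > 0")
    if percent_input_ip <= 0:
        raise InvalidInputError("IP percent input must be > 0")
    return percent_input_ip / percent_input_mock


@dataclass(frozen=True)
class MarkCall:
    gene_id: str
    antibody: str
    percent_input: float
    enrichment: float
    positive: bool
    input_min: float = 1.0
    enr_min: float = 5.0


def score_mark(measurement, input_min: float = 1.0, enr_min: float = 5.0) -> MarkCall:
    """Apply the two-criterion positivity rule to one measurement.

    ``measurement`` is a mapping/row with gene_id, antibody, efficiency,
    Ct_input, Ct_sample, Ct_mock.  Both thresholds are strict: a locus at
    exactly 1% input or exactly 5-fold enrichment is negative.
    """
    m = measurement
    p_ip = percent_input(m["efficiency"], m["Ct_input"], m["Ct_sample"])
    p_mock = percent_input(m["efficiency"], m["Ct_input"], m["Ct_mock"])
    enr = enrichment(p_ip, p_mock)
    return MarkCall(
        gene_id=m["gene_id"], antibody=m["antibody"],
        percent_input=p_ip, enrichment=enr,
        positive=(p_ip > input_min) and (enr > enr_min),
        input_min=input_min, enr_min=enr_min,
    )


def score_table(measurements: pd.DataFrame, input_min: float = 1.0,
                enr_min: float = 5.0) -> pd.DataFrame:
    """MarkCall rows for a whole measurement table."""
    calls = [score_mark(row, input_min, enr_min)
             for _, row in measurements.iterrows()]
    return pd.DataFrame([{
        "gene_id": c.gene_id, "antibody": c.antibody,
        "percent_input": c.percent_input, "enrichment": c.enrichment,
        "positive": c.positive,
    } for c in calls])


def call_bivalent(k4: MarkCall, k27: MarkCall) -> bool:
    """True iff the same gene is positive for both H3K4me3 and H3K27me3."""
    if k4.gene_id != k27.gene_id:
        raise InvalidInputError(
            f"mark calls pair different genes: {k4.gene_id!r} vs {k27.gene_id!r}")
    if {k4.antibody, k27.antibody} != {"H3K4me3", "H3K27me3"}:
        raise InvalidInputError(
            f"bivalency needs one H3K4me3 and one H3K27me3 call, got "
            f"{k4.antibody!r} and {k27.antibody!r}")
    return k4.positive and k27.positive


def screen_gene_sets(
    measurements: pd.DataFrame,
    promoted_set,
    control_set,
    input_min: float = 1.0,
    enr_min: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Score every gene of both sets and tabulate positives per set.

    Returns the per-gene calls and the 2x2 summary counts
    (positives/totals in promoted and control) that feed the Fisher test.
    """
    promoted = set(promoted_set)
    control = set(control_set)
    overlap = promoted & control
    if overlap:
        raise IntegrityError(f"genes in both sets: {sorted(overlap)[:5]}")
    wanted = promoted | control
    present = set(measurements["gene_id"])
    missing = wanted - present
    if missing:
        raise IntegrityError(f"unmeasured genes: {sorted(missing)[:5]}")
    subset = measurements[measurements["gene_id"].isin(wanted)]
    calls = score_table(subset, input_min=input_min, enr_min=enr_min)
    pos = set(calls.loc[calls["positive"], "gene_id"])
    summary = {
        "promoted_positive": len(promoted & pos),
        "promoted_total": len(promoted),
        "control_positive": len(control & pos),
        "control_total": len(control),
    }
    return calls, summary
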