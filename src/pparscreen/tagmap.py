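"""Paired-end tag mapping onto a transcript set, at toy scale.

Filters mirror the original screen: a pair is discarded when its two tags
carry more than 5 N characters in total; each mate may align with at most
one mismatch; mates must land on the same mRNA in convergent orientation
with an outermost span of at most 500 nt; and a pair placing on two or
more mRNAs is discarded as ambiguous.  Valid pairs are counted once per
mRNA as a measure of transcript abundance.

N in a tag acts as a wildcard (matches any base at zero mismatch cost):
this is the only reading under which the ≤5-N admission rule and the
≤1-mismatch rule are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, InvalidInputError
from .simulate import revcomp

REJECTION_REASONS = ("n_filter", "no_hit", "multi_mrna", "too_far")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in seq.upper()), dtype=np.int8,
                       count=len(seq))


@dataclass(frozen=True)
class TagHit:
    """A validated placement of a tag pair on one transcript."""

    pair_id: str
    transcript_id: str
    pos1: int  # 0-based start of the forward mate
    pos2: int  # 0-based start of the reverse mate
    orientation1: str
    orientation2: str
    separation: int  # outermost span in nt
    mismatches1: int
    mismatches2: int


@dataclass(frozen=True)
class Rejection:
    pair_id: str
    reason: str


def pair_n_filter(tag1: str, tag2: str, max_n: int = 5) -> bool:
    """True iff the pair carries at most ``max_n`` N characters in total."""
    return (tag1.upper().count("N") + tag2.upper().count("N")) <= max_n


def match_tag(
    tag: str,
    transcript_seq: str,
    max_mismatch: int = 1,
) -> list[tuple[int, str, int]]:
    """All ungapped placements of ``tag`` on a transcript, both strands.

    Returns (position, strand, mismatches) with strand '+' for the tag as
    given and '-' for its reverse complement; positions are 0-based starts
    of the aligned window on the transcript.  N in the tag matches any
    base at no cost.  A tag longer than the transcript yields no hits.
    """
    L, T = len(tag), len(transcript_seq)
    if L == 0:
        raise InvalidInputError("empty tag")
    if L > T:
        return []
    tseq = _encode(transcript_seq)
    windows = np.lib.stride_tricks.sliding_window_view(tseq, L)
    hits: list[tuple[int, str, int]] = []
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        q = _encode(query)
        informative = q != 4  # N positions never count as mismatches
        mm = ((windows != q) & informative[None, :]).sum(axis=1)
        for pos in np.nonzero(mm <= max_mismatch)[0]:
            hits.append((int(pos), strand, int(mm[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _convergent_placements(
    hits1: Sequence[tuple[int, str, int]],
    hits2: Sequence[tuple[int, str, int]],
    len1: int,
    len2: int,
) -> list[tuple[int, int, str, str, int, int, int]]:
    """Convergent (FR) mate combinations with their outermost span.

    Either mate may be the forward one; the forward mate must start at or
    left of the reverse mate's start.
    """
    out = []
    for p1, s1, m1 in hits1:
        for p2, s2, m2 in hits2:
            if s1 == s2:
                continue
            fwd_pos = p1 if s1 == "+" else p2
            rev_pos = p2 if s1 == "+" else p1
            if fwd_pos > rev_pos:
                continue
            left = min(p1, p2)
            right = max(p1 + len1, p2 + len2)
            out.append((p1, p2, s1, s2, right - left, m1, m2))
    return out


def map_pair(
    pair_id: str,
    tag1: str,
    tag2: str,
    transcripts: pd.DataFrame,
    max_mismatch: int = 1,
    max_separation: int = 500,
    max_n: int = 5,
) -> TagHit | Rejection:
    """Place one tag pair, or reject it with an exhaustive, exclusive reason.

    Reasons: ``n_filter`` (too many Ns), ``no_hit`` (no convergent
    same-transcript placement at all), ``too_far`` (convergent placements
    exist but all span more than ``max_separation`` nt), ``multi_mrna``
    (valid placements on two or more distinct transcripts).  Among several
    placements on the single valid transcript, the one with fewest total
    mismatches wins, ties broken by leftmost pos1 then pos2.
    """
    if transcripts is None or len(transcripts) == 0:
        raise InvalidInputError("empty transcript set")
    if not pair_n_filter(tag1, tag2, max_n=max_n):
        return Rejection(pair_id, "n_filter")

    any_convergent = False
    per_transcript: dict[str, list] = {}
    for _, row in transcripts.iterrows():
        seq = row["sequence"]
        hits1 = match_tag(tag1, seq, max_mismatch)
        if not hits1:
            continue
        hits2 = match_tag(tag2, seq, max_mismatch)
        if not hits2:
            continue
        placements = _convergent_placements(hits1, hits2, len(tag1), len(tag2))
        if placements:
            any_convergent = True
        close = [p for p in placements if p[4] <= max_separation]
        if close:
            per_transcript[row["id"]] = close

    if not per_transcript:
        return Rejection(pair_id, "too_far" if any_convergent else "no_hit")
    if len(per_transcript) > 1:
        return Rejection(pair_id, "multi_mrna")

    (tid, placements), = per_transcript.items()
    p1, p2, s1, s2, span, m1, m2 = min(
        placements, key=lambda p: (p[5] + p[6], p[0], p[1])
    )
    return TagHit(pair_id, tid, p1, p2, s1, s2, span, m1, m2)


def map_pairs(
    pairs: pd.DataFrame,
    transcripts: pd.DataFrame,
    max_mismatch: int = 1,
    max_separation: int = 500,
    max_n: int = 5,
) -> tuple[list[TagHit], list[Rejection]]:
    """Map every (pair_id, tag1, tag2) row; valid + rejected = input."""
    hits, rejections = [], []
    for _, row in pairs.iterrows():
        result = map_pair(row["pair_id"], row["tag1"], row["tag2"], transcripts,
                          max_mismatch=max_mismatch,
                          max_separation=max_separation, max_n=max_n)
        (hits if isinstance(result, TagHit) else rejections).append(result)
    return hits, rejections


def count_tags(hits: Iterable[TagHit], transcripts: pd.DataFrame) -> pd.Series:
    """Valid pairs per transcript (zero-filled); the abundance measure."""
    ids = list(transcripts["id"])
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate transcript ids")
    counts = pd.Series(0, index=pd.Index(ids, name="gene"), dtype=int)
    for hit in hits:
        if hit.transcript_id not in counts.index:
            raise IntegrityError(f"hit references unknown transcript {hit.transcript_id!r}")
        counts[hit.transcript_id] += 1
    return counts


def hits_frame(hits: Sequence[TagHit]) -> pd.DataFrame:
    """Tabular view of valid hits for TSV export."""
    return pd.DataFrame([{
        "pair_id": h.pair_id, "transcript": h.transcript_id,
        "pos1": h.pos1, "pos2": h.pos2, "separation": h.separation,
        "mm1": h.mismatches1, "mm2": h.mismatches2,
    } for h in hits], columns=["pair_id", "transcript", "pos1", "pos2",
                               "separation", "mm1", "mm2"])


def rejections_frame(rejections: Sequence[Rejection]) -> pd.DataFrame:
    return pd.DataFrame([{"pair_id": r.pair_id, "reason": r.reason}
                         for r in rejections], columns=["pair_id", "reason"])
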