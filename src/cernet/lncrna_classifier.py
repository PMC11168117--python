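"""Positional classification of lncRNA candidates against coding genes.

Each candidate transcript receives exactly one of five categories by a
fixed precedence:

1. ``sense_overlapping`` — same strand, at least 1 bp of exonic overlap
   with a coding exon;
2. ``intronic`` — same strand, fully contained within a single intron of a
   coding transcript, with no exon overlap;
3. ``antisense`` — opposite strand, any genomic-span overlap;
4. ``bidirectional`` — no overlap at all, but the candidate's transcription
   start site lies within ``bidirectional_window`` bp of a coding TSS on the
   opposite strand (a divergent-promoter arrangement);
5. ``intergenic`` — everything else.

All interval arithmetic is on 1-based closed coordinates.  Precedence is
total, so permuting the coding list never changes a label, and setting the
bidirectional window to 0 reclassifies bidirectional calls as intergenic
without touching any other class.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import TranscriptModel

__all__ = ["LncCategory", "classify_lncrna", "classify_all", "write_classification"]

DEFAULT_BIDIRECTIONAL_WINDOW = 1000


class LncCategory(str, enum.Enum):
    intergenic = "intergenic"
    bidirectional = "bidirectional"
    intronic = "intronic"
    antisense = "antisense"
    sense_overlapping = "sense_overlapping"


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def classify_lncrna(
    candidate: TranscriptModel,
    coding: Sequence[TranscriptModel],
    bidirectional_window: int = DEFAULT_BIDIRECTIONAL_WINDOW,
) -> LncCategory:
    """Assign one positional category to a candidate lncRNA transcript.

    Only coding models on the candidate's chromosome are considered; a
    candidate alone on its chromosome is intergenic.
    """
    same_chrom = [t for t in coding if t.chrom == candidate.chrom]
    cand_span = candidate.span

    # 1. sense_overlapping: exon-level overlap on the same strand
    for t in same_chrom:
        if t.strand != candidate.strand:
            continue
        for ce in t.exons:
            if any(_intervals_overlap(ce, e) for e in candidate.exons):
                return LncCategory.sense_overlapping

    # 2. intronic: same strand, whole span inside one intron
    for t in same_chrom:
        if t.strand != candidate.strand:
            continue
        for istart, iend in t.introns:
            if istart <= cand_span[0] and cand_span[1] <= iend:
                return LncCategory.intronic

    # 3. antisense: opposite strand, genomic spans overlap
    for t in same_chrom:
        if t.strand != candidate.strand and _intervals_overlap(t.span, cand_span):
            return LncCategory.antisense

    # 4. bidirectional: no span overlap anywhere, divergent TSSs within window
    if not any(_intervals_overlap(t.span, cand_span) for t in same_chrom):
        for t in same_chrom:
            if (
                t.strand != candidate.strand
                and abs(t.tss - candidate.tss) <= bidirectional_window
            ):
                return LncCategory.bidirectional

    return LncCategory.intergenic


def classify_all(
    candidates: Iterable[TranscriptModel],
    coding: Sequence[TranscriptModel],
    bidirectional_window: int = DEFAULT_BIDIRECTIONAL_WINDOW,
) -> dict[str, LncCategory]:
    return {
        c.transcript_id: classify_lncrna(c, coding, bidirectional_window)
        for c in candidates
    }


def write_classification(labels: dict[str, LncCategory], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcategory\n")
        for tid in sorted(labels):
            fh.write(f"{tid}\t{labels[tid].value}\n")
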