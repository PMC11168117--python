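"""Small-RNA tag filtering and priority-ordered annotation.

Raw small-RNA tags are screened with four rules before annotation: minimum
length 18 nt, mean base quality above Q20 (when quality information exists),
no residual adapter, and no polyA homopolymer artifact.  Surviving tags are
assigned a single category from a fixed priority order in which structural
RNA hits (rRNA/scRNA/snoRNA/snRNA/tRNA, bundled as one category) outrank
miRNA annotations, which outrank genomic context; a tag matching nothing is
recorded as unannotated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["SmallRnaTag", "TagCategory", "filter_small_rna_tags", "annotate_tag",
           "write_rejection_report"]

_ALPHABET = set("ACGTUN")

#: fraction of A (or U/T read as A-tail) above which a tag counts as polyA
POLYA_FRACTION = 0.8


@dataclass
class SmallRnaTag:
    """A sequenced small-RNA tag with optional quality and adapter flags."""

    sequence: str
    mean_quality: float | None = None
    has_adapter: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty tag sequence")
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)} in tag")


class TagCategory(enum.IntEnum):
    """Annotation categories, numbered by descending priority."""

    rRNA_like = 1       # rRNA / scRNA / snoRNA / snRNA / tRNA bundle
    exist_miRNA = 2
    exist_miRNA_edit = 3
    known_miRNA = 4
    repeat = 5
    exon = 6
    novel_miRNA = 7
    intron = 8
    unann = 9


def _reject_reason(tag: SmallRnaTag) -> str | None:
    """First failing filter rule, or None if the tag is clean."""
    if tag.mean_quality is not None and tag.mean_quality <= 20:
        return "low_quality"
    if tag.has_adapter:
        return "adapter"
    if len(tag.sequence) < 18:
        return "length"
    seq = tag.sequence.upper()
    if seq.count("A") / len(seq) >= POLYA_FRACTION:
        return "polyA"
    return None


def filter_small_rna_tags(
    tags: Iterable[SmallRnaTag],
) -> tuple[list[SmallRnaTag], list[tuple[SmallRnaTag, str]]]:
    """Split tags into kept and rejected, each rejection tagged with the
    first rule it failed (low_quality, adapter, length, polyA)."""
    kept: list[SmallRnaTag] = []
    rejected: list[tuple[SmallRnaTag, str]] = []
    for tag in tags:
        reason = _reject_reason(tag)
        if reason is None:
            kept.append(tag)
        else:
            rejected.append((tag, reason))
    return kept, rejected


def annotate_tag(membership: Iterable[TagCategory]) -> TagCategory:
    """Resolve a tag's annotation as the highest-priority category it hits.

    ``membership`` holds every category the tag matched; an empty set means
    the tag matched nothing and is recorded as :attr:`TagCategory.unann`.
    """
    members = set(membership)
    if TagCategory.unann in members:
        raise ValueError("unann is the absence of membership, not a candidate")
    if not members:
        return TagCategory.unann
    return min(members)


def write_rejection_report(
    rejected: Sequence[tuple[SmallRnaTag, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("tag\treason\n")
        for tag, reason in rejected:
            fh.write(f"{tag.sequence}\t{reason}\n")
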