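r"""Canonical seed-match miRNA target prediction.

A target site is a stretch of the target transcript complementary to the
miRNA seed (miRNA positions 2-7, numbered 5'->3').  In target 5'->3'
orientation a site reads::

    [m8 complement] [complement of positions 7..2] [A opposite position 1]
     \- 7mer-m8 -/   \------- 6mer core -------/    \---- 7mer-A1 ----/

giving the standard hierarchy 8mer > 7mer-m8 > 7mer-A1 > 6mer; the A
opposite position 1 is recognized as a literal A regardless of the miRNA's
first base.  Whole transcripts are scanned (lncRNA/circRNA sponges carry no
UTR annotation), U and T are treated as equivalent, and the strongest site
type is reported once per locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "SeedSite",
    "TargetMap",
    "SITE_TYPE_ORDER",
    "reverse_complement",
    "find_seed_sites",
    "build_target_map",
    "write_site_table",
]

#: site types, weakest to strongest
SITE_TYPE_ORDER = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTUN")


@dataclass(frozen=True)
class SeedSite:
    """One seed-match locus on a target transcript (1-based position)."""

    mirna_id: str
    target_id: str
    site_type: str
    position: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPE_ORDER:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass
class TargetMap:
    """miRNA -> set of targets with at least one admissible seed site."""

    targets_of: dict[str, set[str]] = field(default_factory=dict)
    sites: list[SeedSite] = field(default_factory=list)

    def pairs(self) -> set[tuple[str, str]]:
        return {(m, t) for m, ts in self.targets_of.items() for t in ts}


def _normalize(seq: str, label: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{label}: invalid characters {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_seed_sites(
    mirna_seq: str, target_seq: str, mirna_id: str = "mirna", target_id: str = "target"
) -> list[SeedSite]:
    """Scan a target transcript for canonical seed sites of one miRNA.

    Both sequences are 5'->3'.  Sites are located by their 6mer core
    (reverse complement of miRNA positions 2-7) and widened to 7mer-m8 /
    7mer-A1 / 8mer where the flanking matches hold; only the strongest type
    is reported per core locus.  Position is the 1-based start of the full
    site on the target.
    """
    mirna = _normalize(mirna_seq, "mirna_seq")
    target = _normalize(target_seq, "target_seq")
    if len(mirna) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt")
    core = reverse_complement(mirna[1:7])      # positions 2-7
    m8_complement = mirna[7].translate(_COMPLEMENT)  # pairs 5' of core on target

    sites: list[SeedSite] = []
    start = target.find(core)
    while start != -1:
        has_m8 = start >= 1 and target[start - 1] == m8_complement
        has_a1 = start + 6 < len(target) and target[start + 6] == "A"
        if has_m8 and has_a1:
            site_type, pos = "8mer", start - 1
        elif has_m8:
            site_type, pos = "7mer-m8", start - 1
        elif has_a1:
            site_type, pos = "7mer-A1", start
        else:
            site_type, pos = "6mer", start
        sites.append(SeedSite(mirna_id, target_id, site_type, pos + 1))
        start = target.find(core, start + 1)
    return sites


def build_target_map(
    de_mirnas: Sequence[str],
    mirna_sequences: Mapping[str, str],
    target_sequences: Mapping[str, str],
    min_site_type: str = "7mer-m8",
) -> TargetMap:
    """Predict targets for the differential miRNAs by seed matching.

    ``min_site_type`` drops sites weaker than the given type (default
    7mer-m8, which limits false positives at transcript scale).  A DE miRNA
    without a sequence is skipped with a warning.
    """
    if min_site_type not in SITE_TYPE_ORDER:
        raise ValueError(f"unknown site type {min_site_type!r}")
    min_rank = SITE_TYPE_ORDER.index(min_site_type)
    tmap = TargetMap()
    for mirna_id in de_mirnas:
        seq = mirna_sequences.get(mirna_id)
        if seq is None:
            warnings.warn(f"DE miRNA {mirna_id!r} has no sequence; skipped")
            continue
        for target_id, target_seq in target_sequences.items():
            kept = [
                s
                for s in find_seed_sites(seq, target_seq, mirna_id, target_id)
                if SITE_TYPE_ORDER.index(s.site_type) >= min_rank
            ]
            if kept:
                tmap.targets_of.setdefault(mirna_id, set()).add(target_id)
                tmap.sites.extend(kept)
    return tmap


def write_site_table(tmap: TargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\ttarget\tsite_type\tposition\n")
        for s in sorted(
            tmap.sites, key=lambda s: (s.mirna_id, s.target_id, s.position)
        ):
            fh.write(f"{s.mirna_id}\t{s.target_id}\t{s.site_type}\t{s.position}\n")
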