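"""Self-contained synthetic scenarios for exercising the whole pipeline.

A scenario emulates the study design the pipeline targets: two conditions
(groupA = laying-type, groupB = broody-type ovaries) with a configurable
number of replicates (default 3 vs 3), count matrices for four RNA classes,
transcript sequences, transcript models, and a ground-truth record of what
was planted.

Statistical structure
---------------------
* Counts are negative binomial with per-feature base means (log-normal
  spread around ``base_mean``), a common dispersion, and per-sample
  library-size factors drawn log-normal(0, 0.1).
* A planted ceRNA triplet (ce, miRNA, mRNA) gets: a differentially
  expressed miRNA (symmetric +-``de_log2fc``/2 shift per group); targets
  whose NB means are modulated by exp(-coupling_strength * z), z being the
  miRNA's standardized realized log-signal — producing negative
  miRNA-target rank correlation and positive ce-mRNA correlation in
  expectation; and an explicit opposite-direction DE shift on the targets
  so all three members pass the DE gate even at zero coupling.
* Planted ceRNAs alternate between lncRNA and circRNA so both network
  flavours appear.
* Every target-class sequence is first sampled clean of ALL miRNA 6mer
  seed cores (rejection sampling with a bounded deterministic repair
  fallback for large scenarios); planted targets then receive exactly one
  8mer site for their miRNA.  Predicted target relations therefore match
  the planted ones exactly, so recovery scores measure the statistical
  filters, not accidental sequence matches.
* Transcript models place lncRNAs into all five positional categories
  (cycling sense_overlapping, intronic, antisense, bidirectional,
  intergenic) anchored to the protein-coding gene models.

The same seed always reproduces bit-identical scenarios and fixture files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, TranscriptModel, write_counts, write_fasta
from .target_prediction import reverse_complement

__all__ = [
    "ConfigurationError",
    "ScenarioConfig",
    "TruthSet",
    "Scenario",
    "generate_scenario",
    "write_fixture",
    "load_fixture",
]

GROUP_A = "groupA"
GROUP_B = "groupB"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of a synthetic scenario; defaults emulate a 3-vs-3 design."""

    n_replicates_per_group: int = 3
    n_mirna: int = 40
    n_mrna: int = 60
    n_lncrna: int = 50
    n_circrna: int = 30
    n_planted_triplets: int = 10
    n_planted_de_per_class: int = 5
    base_mean: float = 500.0
    nb_dispersion: float = 0.1
    coupling_strength: float = 2.0
    de_log2fc: float = 2.0
    target_length: int = 300
    mirna_length: int = 22
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates_per_group < 2:
            raise ConfigurationError("need at least 2 replicates per group")
        for name in ("n_mirna", "n_mrna", "n_lncrna", "n_circrna"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_planted_triplets < 0:
            raise ConfigurationError("n_planted_triplets must be >= 0")
        if self.n_planted_triplets > min(self.n_lncrna, self.n_mrna):
            raise ConfigurationError(
                "n_planted_triplets exceeds min(n_lncrna, n_mrna)"
            )
        if self.n_planted_triplets > self.n_mirna:
            raise ConfigurationError("need one miRNA per planted triplet")
        if self.n_planted_de_per_class < 0:
            raise ConfigurationError("n_planted_de_per_class must be >= 0")
        if self.base_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("base_mean and nb_dispersion must be > 0")
        if self.coupling_strength < 0:
            raise ConfigurationError("coupling_strength must be >= 0")
        if self.de_log2fc < 0:
            raise ConfigurationError("de_log2fc must be >= 0")
        if self.mirna_length < 8:
            raise ConfigurationError("mirna_length must be >= 8")
        if self.target_length < 30:
            raise ConfigurationError("target_length must be >= 30")


@dataclass
class TruthSet:
    """What was planted: DE features, ceRNA triplets and target pairs."""

    planted_de: set[tuple[str, str, str]] = field(default_factory=set)
    planted_triplets: set[tuple[str, str, str]] = field(default_factory=set)
    planted_target_pairs: set[tuple[str, str]] = field(default_factory=set)

    def validate(self, de_planted: bool = True) -> None:
        de_ids = {fid for fid, _, _ in self.planted_de}
        for ce, mirna, mrna in self.planted_triplets:
            if de_planted:
                for member in (ce, mirna, mrna):
                    if member not in de_ids:
                        raise AssertionError(
                            f"triplet member {member} not in planted_de"
                        )
            for pair in ((mirna, ce), (mirna, mrna)):
                if pair not in self.planted_target_pairs:
                    raise AssertionError(f"target pair {pair} missing")


@dataclass
class Scenario:
    config: ScenarioConfig
    counts: dict[str, CountMatrix]
    sequences: dict[str, str]
    transcripts: list[TranscriptModel]
    truth: TruthSet

    @property
    def condition_of(self) -> dict[str, str]:
        return next(iter(self.counts.values())).condition_of


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _foreign_hits(seq: str, cores: frozenset[str], allowed: int | None):
    """Start positions of every forbidden 6-gram occurrence.

    ``allowed`` optionally names the position of the designed seed site's
    core, which must be kept.
    """
    return [
        p
        for p in range(len(seq) - 5)
        if seq[p : p + 6] in cores and p != allowed
    ]


def _clean_seq(
    rng: np.random.Generator,
    length: int,
    cores: frozenset[str],
    max_reject: int = 20,
) -> str:
    """A random sequence containing none of the given seed cores.

    Pure rejection sampling first; if ``max_reject`` draws all fail, or a
    draw shows the core set is too dense for rejection to ever succeed
    (many simultaneous hits), the last draw is repaired by deterministic
    point substitutions inside each hit.
    """
    seq = ""
    for _ in range(max_reject):
        seq = _random_seq(rng, length)
        hits = _foreign_hits(seq, cores, None)
        if not hits:
            return seq
        if len(hits) > 8:  # acceptance probability ~0; repair instead
            break
    return _repair(seq, cores, None)


def _repair(seq: str, cores: frozenset[str], allowed: int | None) -> str:
    """Break every forbidden 6-gram by point substitution.

    Hits are removed one at a time; among all admissible single-base
    substitutions inside the hit, the one leaving the fewest forbidden
    6-grams in the surrounding window is applied (ties to the first), so
    each step makes progress and repaired regions are not re-poisoned.
    A hit nested wholly inside the protected designed site is left alone.
    """
    protected = range(0)
    if allowed is not None:
        protected = range(allowed - 1, allowed + 7)  # full 8mer site
    chars = list(seq)

    def local_hits(pos: int) -> int:
        lo = max(0, pos - 5)
        hi = min(len(chars) - 6, pos)
        window = "".join(chars[lo : hi + 6])
        return sum(
            1
            for q in range(hi - lo + 1)
            if window[q : q + 6] in cores and (lo + q) != allowed
        )

    for _ in range(10 * len(seq)):
        current = "".join(chars)
        hits = [
            p
            for p in _foreign_hits(current, cores, allowed)
            if any(p + o not in protected for o in range(6))
        ]
        if not hits:
            return current
        start = hits[0]
        best = None
        for offset in range(6):
            pos = start + offset
            if pos in protected:
                continue
            original = chars[pos]
            for base in "ACGT":
                if base == original:
                    continue
                chars[pos] = base
                score = local_hits(pos)
                if best is None or score < best[0]:
                    best = (score, pos, base)
            chars[pos] = original
        _, pos, base = best
        chars[pos] = base
    raise RuntimeError("sequence repair did not converge")  # pragma: no cover


def _mirna_core(seq: str) -> str:
    """Reverse complement of seed positions 2-7 (the 6mer core on targets)."""
    return reverse_complement(seq[1:7])


def _eight_mer_site(mirna_seq: str) -> str:
    """Perfect 8mer site: complement of positions 2-8 plus the A1 anchor."""
    return reverse_complement(mirna_seq[1:8]) + "A"


# ---------------------------------------------------------------------------
# generator


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}-{i + 1:04d}" for i in range(n)]


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate one fully self-contained scenario from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_replicates_per_group
    samples = [f"A{i + 1}" for i in range(n_rep)] + [
        f"B{i + 1}" for i in range(n_rep)
    ]
    condition_of = {s: (GROUP_A if s.startswith("A") else GROUP_B) for s in samples}
    group_sign = np.array([-0.5 if s.startswith("A") else 0.5 for s in samples])

    ids = {
        "miRNA": _feature_ids("mir", config.n_mirna),
        "mRNA": _feature_ids("gene", config.n_mrna),
        "lncRNA": _feature_ids("lnc", config.n_lncrna),
        "circRNA": _feature_ids("circ", config.n_circrna),
    }

    # --- miRNA sequences with pairwise-distinct seed cores
    mirna_seqs: dict[str, str] = {}
    seen_cores: set[str] = set()
    for mid in ids["miRNA"]:
        while True:
            seq = _random_seq(rng, config.mirna_length)
            if _mirna_core(seq) not in seen_cores:
                break
        seen_cores.add(_mirna_core(seq))
        mirna_seqs[mid] = seq
    cores = frozenset(_mirna_core(s) for s in mirna_seqs.values())

    # --- plant triplets: (ce, miRNA, mRNA); ce alternates lncRNA/circRNA
    truth = TruthSet()
    lnc_cursor = circ_cursor = 0
    planted_members: dict[str, tuple[str, int]] = {}  # fid -> (class, +-1 dir)
    triplet_of_mirna: dict[str, tuple[str, str]] = {}
    for i in range(config.n_planted_triplets):
        mirna = ids["miRNA"][i]
        use_circ = i % 2 == 1 and circ_cursor < config.n_circrna
        if use_circ:
            ce, ce_class = ids["circRNA"][circ_cursor], "circRNA"
            circ_cursor += 1
        else:
            ce, ce_class = ids["lncRNA"][lnc_cursor], "lncRNA"
            lnc_cursor += 1
        mrna = ids["mRNA"][i]
        # alternate at half the rate of the lncRNA/circRNA alternation so
        # each ce class receives both directions; keeping planted shifts
        # balanced within a class protects the per-class library sizes from
        # compositional drift
        direction = 1 if (i // 2) % 2 == 0 else -1  # miRNA up/down in groupB
        truth.planted_triplets.add((ce, mirna, mrna))
        truth.planted_target_pairs.add((mirna, ce))
        truth.planted_target_pairs.add((mirna, mrna))
        planted_members[mirna] = ("miRNA", direction)
        planted_members[ce] = (ce_class, -direction)
        planted_members[mrna] = ("mRNA", -direction)
        triplet_of_mirna[mirna] = (ce, mrna)

    # --- extra planted DE decoys per class (not in any triplet)
    extra_de: dict[str, tuple[str, int]] = {}
    for rna_class, class_ids in ids.items():
        free = [f for f in class_ids if f not in planted_members]
        for j, fid in enumerate(free[: config.n_planted_de_per_class]):
            extra_de[fid] = (rna_class, 1 if j % 2 == 0 else -1)

    de_of = {**planted_members, **extra_de}
    if config.de_log2fc > 0:
        truth.planted_de = {
            (fid, rna_class, "up" if d > 0 else "down")
            for fid, (rna_class, d) in de_of.items()
        }
    truth.validate(de_planted=config.de_log2fc > 0)

    # --- count generation
    size_factor = np.exp(rng.normal(0.0, 0.1, size=len(samples)))
    inv_dispersion = 1.0 / config.nb_dispersion

    def nb_draw(mean_matrix: np.ndarray) -> np.ndarray:
        p = inv_dispersion / (inv_dispersion + mean_matrix)
        return rng.negative_binomial(inv_dispersion, p)

    def base_means(n: int) -> np.ndarray:
        return config.base_mean * np.exp(rng.normal(0.0, 0.5, size=n))

    def de_shift(fid: str) -> np.ndarray:
        if fid in de_of and config.de_log2fc > 0:
            return 2.0 ** (de_of[fid][1] * config.de_log2fc * group_sign)
        return np.ones(len(samples))

    # miRNAs first: their realized signal drives the planted targets
    mu_mirna = base_means(config.n_mirna)[:, None] * size_factor[None, :]
    for row, fid in enumerate(ids["miRNA"]):
        mu_mirna[row] *= de_shift(fid)
    counts_mirna = nb_draw(mu_mirna)

    modulation: dict[str, np.ndarray] = {}
    for row, fid in enumerate(ids["miRNA"]):
        if fid not in triplet_of_mirna:
            continue
        signal = np.log1p(counts_mirna[row].astype(float) / size_factor)
        sd = signal.std()
        z = (signal - signal.mean()) / sd if sd > 0 else np.zeros_like(signal)
        mod = np.exp(-config.coupling_strength * z)
        ce, mrna = triplet_of_mirna[fid]
        modulation[ce] = mod
        modulation[mrna] = mod

    counts: dict[str, CountMatrix] = {}
    counts["miRNA"] = CountMatrix(
        pd.DataFrame(counts_mirna, index=ids["miRNA"], columns=samples),
        "miRNA",
        condition_of,
    )
    for rna_class in ("mRNA", "lncRNA", "circRNA"):
        class_ids = ids[rna_class]
        mu = base_means(len(class_ids))[:, None] * size_factor[None, :]
        for row, fid in enumerate(class_ids):
            mu[row] *= de_shift(fid)
            if fid in modulation:
                mu[row] *= modulation[fid]
        counts[rna_class] = CountMatrix(
            pd.DataFrame(nb_draw(mu), index=class_ids, columns=samples),
            rna_class,
            condition_of,
        )

    # --- target-class sequences: clean backgrounds, then designed sites
    site_of = {}  # target id -> mirna id
    for mirna, (ce, mrna) in triplet_of_mirna.items():
        site_of[ce] = mirna
        site_of[mrna] = mirna
    sequences: dict[str, str] = dict(mirna_seqs)
    for rna_class in ("mRNA", "lncRNA", "circRNA"):
        for fid in ids[rna_class]:
            seq = _clean_seq(rng, config.target_length, cores)
            if fid in site_of:
                site = _eight_mer_site(mirna_seqs[site_of[fid]])
                pos = config.target_length // 2
                seq = seq[:pos] + site + seq[pos + len(site):]
                # the designed core sits one base into the 8mer site
                seq = _repair(seq, cores, pos + 1)
            sequences[fid] = seq

    transcripts = _transcript_models(ids)
    return Scenario(config, counts, sequences, transcripts, truth)


def _transcript_models(ids: dict[str, list[str]]) -> list[TranscriptModel]:
    """Protein-coding gene models plus lncRNAs cycling all five positional
    categories, laid out deterministically on one chromosome."""
    models: list[TranscriptModel] = []
    n_mrna = len(ids["mRNA"])
    anchors = []
    for g, fid in enumerate(ids["mRNA"]):
        start = 100_000 + g * 50_000
        exons = [
            (start, start + 500),
            (start + 2_000, start + 2_500),
            (start + 9_000, start + 9_500),
        ]
        anchors.append(start)
        models.append(
            TranscriptModel(fid, f"{fid}.g", "chr1", "+", exons, "protein_coding")
        )
    categories = ("sense_overlapping", "intronic", "antisense", "bidirectional",
                  "intergenic")
    for j, fid in enumerate(ids["lncRNA"]):
        category = categories[j % 5]
        start = anchors[(j // 5) % n_mrna]
        k = 10 * (j // (5 * n_mrna))  # small shift when anchors are reused
        if category == "sense_overlapping":
            exons, strand = [(start + 400 + k, start + 800 + k)], "+"
        elif category == "intronic":
            exons, strand = [(start + 600 + k, start + 900 + k)], "+"
        elif category == "antisense":
            exons, strand = [(start + 100 + k, start + 700 + k)], "-"
        elif category == "bidirectional":
            exons, strand = [(start - 1_200 - k, start - 400 - k)], "-"
        else:  # intergenic: mid-gap, far from every TSS
            exons, strand = [(start + 20_000 + k, start + 20_500 + k)], "+"
        models.append(
            TranscriptModel(fid, f"{fid}.g", "chr1", strand, exons,
                            "lncRNA_candidate")
        )
    return models


# ---------------------------------------------------------------------------
# fixture writing / loading


def write_fixture(scenario: Scenario, directory: str | Path) -> dict[str, Path]:
    """Write a scenario as plain-text files; rereading reproduces it exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for rna_class, matrix in scenario.counts.items():
        path = directory / f"counts_{rna_class}.tsv"
        write_counts(matrix, path)
        paths[f"counts_{rna_class}"] = path

    path = directory / "condition_map.tsv"
    with open(path, "w") as fh:
        for sample, condition in scenario.condition_of.items():
            fh.write(f"{sample}\t{condition}\n")
    paths["condition_map"] = path

    paths["fasta"] = directory / "sequences.fasta"
    write_fasta(scenario.sequences, paths["fasta"])

    paths["gtf"] = directory / "annotation.gtf"
    with open(paths["gtf"], "w") as fh:
        for t in scenario.transcripts:
            for start, end in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    f"chr1\tcernet\texon\t{start}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                )

    paths["truth"] = directory / "truth.json"
    truth = {
        "planted_de": sorted(list(t) for t in scenario.truth.planted_de),
        "planted_triplets": sorted(
            list(t) for t in scenario.truth.planted_triplets
        ),
        "planted_target_pairs": sorted(
            list(t) for t in scenario.truth.planted_target_pairs
        ),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def load_fixture(directory: str | Path):
    """Reload a written fixture: (counts per class, sequences, transcripts,
    TruthSet)."""
    from .io_formats import load_counts, load_fasta, load_transcripts

    directory = Path(directory)
    counts = {
        rna_class: load_counts(
            directory / f"counts_{rna_class}.tsv",
            directory / "condition_map.tsv",
            rna_class,
        )
        for rna_class in ("miRNA", "mRNA", "lncRNA", "circRNA")
    }
    sequences = load_fasta(directory / "sequences.fasta")
    transcripts = load_transcripts(directory / "annotation.gtf")
    with open(directory / "truth.json") as fh:
        raw = json.load(fh)
    truth = TruthSet(
        planted_de={tuple(t) for t in raw["planted_de"]},
        planted_triplets={tuple(t) for t in raw["planted_triplets"]},
        planted_target_pairs={tuple(t) for t in raw["planted_target_pairs"]},
    )
    return counts, sequences, transcripts, truth
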