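"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design this package analyses: a repeat
library of TE families, a genome carrying diverged copies of each family,
a low-coverage genome skim, a retrotransposon transcript set with ordered
protein-domain architectures and replicated counts, and a small-RNA pool
mixing TE-derived piRNAs (23-31 nt, 1U-enriched, sense/antisense),
hairpin-derived miRNAs (~22 nt) and rRNA/tRNA-like contaminants.

Mutation model: each consensus position mutates independently with
probability ``d`` (the family's divergence); a mutated site becomes a
transition with probability ``kappa / (kappa + 2)`` and otherwise one of
the two transversions.  The realized mismatch fraction of a copy against
its consensus therefore equals ``d`` in expectation.  There are no indels
and no nested insertions, matching the ungapped alignment contract.

All operations are deterministic given their seed; child streams are
derived with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import SequenceRecord, TERecord, revcomp

__all__ = [
    "FamilySpec",
    "GenomeModel",
    "TranscriptSpec",
    "SmallRNASpec",
    "SkimSimulation",
    "TranscriptomeSimulation",
    "SmallRNASimulation",
    "PG_TO_BP",
    "DEFAULT_PIRNA_LEN_DIST",
    "simulate_te_library",
    "simulate_genome_and_reads",
    "simulate_transcriptome",
    "simulate_small_rna",
    "random_references",
]

#: Cytogenetic conversion constant: 1 pg of DNA = 978 Mbp.
PG_TO_BP = 978_000_000

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default piRNA length distribution (nt -> probability), peaking at 27-28 nt
#: as in locust testis small-RNA pools.
DEFAULT_PIRNA_LEN_DIST: dict[int, float] = {
    23: 0.04, 24: 0.05, 25: 0.08, 26: 0.14, 27: 0.24,
    28: 0.22, 29: 0.13, 30: 0.07, 31: 0.03,
}


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _child_rngs(seed: int | np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


@dataclass(frozen=True)
class FamilySpec:
    """Generative description of one TE family.

    ``divergence`` is either a single substitution fraction or a mixture
    given as ``[(d1, w1), (d2, w2), ...]`` (weights summing to 1); mixtures
    are how bimodal "ancient + recent burst" landscapes are produced.
    """

    id: str
    subclass: str = "LTR"
    superfamily: str | None = None
    consensus_len: int = 5000
    copy_number: int = 100
    divergence: float | Sequence[tuple[float, float]] = 0.10
    kappa: float = 2.0

    def __post_init__(self) -> None:
        for d, _w in self._mixture():
            if not 0.0 <= d <= 0.35:
                raise ValueError(f"{self.id}: divergence {d} outside [0, 0.35]")
        if self.copy_number < 0:
            raise ValueError(f"{self.id}: copy_number must be >= 0")
        if self.kappa <= 0:
            raise ValueError(f"{self.id}: kappa must be > 0")

    def _mixture(self) -> list[tuple[float, float]]:
        if isinstance(self.divergence, (int, float)):
            return [(float(self.divergence), 1.0)]
        return [(float(d), float(w)) for d, w in self.divergence]


@dataclass(frozen=True)
class GenomeModel:
    """Haploid genome size and background composition for the skim simulator."""

    genome_size_pg: float | None = None
    genome_size_bp: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size_pg is None and self.genome_size_bp is None:
            raise ValueError("provide genome_size_pg or genome_size_bp")

    @property
    def size_bp(self) -> int:
        if self.genome_size_bp is not None:
            return int(self.genome_size_bp)
        return int(round(self.genome_size_pg * PG_TO_BP))


@dataclass(frozen=True)
class TranscriptSpec:
    """One retrotransposon transcript: domain architecture and expression."""

    id: str
    architecture: tuple[str, ...]
    true_subclass: str = "unclassified"
    clade: str | None = None
    length: int = 3000
    mean_count: float | Mapping[str, float] = 100.0
    dispersion: float = 0.1
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.architecture:
            raise ValueError(f"{self.id}: architecture must be non-empty")
        bad = set(self.architecture) - {"GAG", "PROT", "INT", "RT", "RH"}
        if bad:
            raise ValueError(f"{self.id}: unknown domains {sorted(bad)}")


@dataclass(frozen=True)
class SmallRNASpec:
    """Composition of a simulated small-RNA pool.

    Class counts are exact (rounded products of the fractions); stochastic
    choices are per-read: source family, position, strand, length, and the
    5' base.  The first base of a piRNA read is forced to T (DNA-space U)
    with probability ``u1_prob`` and to a uniformly chosen non-T base
    otherwise, so the emitted 1U fraction equals ``u1_prob`` exactly in
    expectation.
    """

    n_reads: int = 10000
    pirna_fraction: float = 0.3
    mirna_fraction: float = 0.4
    contaminant_fraction: float = 0.1
    pirna_len_dist: Mapping[int, float] | None = None
    mirna_len: int = 22
    u1_prob: float = 0.8
    antisense_fraction: float = 0.5
    family_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        fracs = (self.pirna_fraction, self.mirna_fraction, self.contaminant_fraction)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
        if not 0 <= self.u1_prob <= 1:
            raise ValueError("u1_prob must lie in [0,1]")
        dist = self.pirna_len_dist or DEFAULT_PIRNA_LEN_DIST
        if any(not 23 <= length <= 31 for length in dist):
            raise ValueError("piRNA lengths must lie in 23..31")


# ---------------------------------------------------------------------------
# library and genome


def simulate_te_library(specs: Sequence[FamilySpec], seed: int) -> list[TERecord]:
    """One uniformly random consensus per family spec, deterministic in seed."""
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("family ids must be unique")
    out = []
    for spec, rng in zip(specs, _child_rngs(seed, len(specs))):
        seq = _decode(_random_codes(rng, spec.consensus_len))
        out.append(TERecord(spec.id, spec.subclass, spec.superfamily, seq))
    return out


def _mutate(codes: np.ndarray, d: float, kappa: float,
            rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Substitute each site with prob d; transitions with prob kappa/(kappa+2).

    Transition partner of code c is ``c ^ 2`` (A<->G, C<->T); the two
    transversion partners are ``c ^ 1`` and ``c ^ 3``.
    """
    out = codes.copy()
    hit = np.nonzero(rng.random(codes.size) < d)[0]
    if hit.size:
        is_ts = rng.random(hit.size) < kappa / (kappa + 2.0)
        mask = np.where(is_ts, 2, np.where(rng.random(hit.size) < 0.5, 1, 3))
        out[hit] = out[hit] ^ mask.astype(np.uint8)
    return out, hit.size / codes.size


@dataclass
class SkimSimulation:
    """Reads plus the truth tables that score every downstream stage."""

    reads: list[SequenceRecord]
    family_truth: pd.DataFrame
    copy_truth: pd.DataFrame
    genome_size_bp: int
    total_read_bases: int


def simulate_genome_and_reads(
    model: GenomeModel,
    library: Sequence[TERecord],
    specs: Sequence[FamilySpec],
    coverage: float,
    read_len: int = 150,
    seed: int = 0,
) -> SkimSimulation:
    """Insert diverged TE copies into random background and sample a skim.

    The number of reads is the rounded expectation
    ``coverage * genome_size / read_len``; read start positions and strands
    are uniform.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    G = model.size_bp
    lib = {r.id: r for r in library}
    rng_copies, rng_bg, rng_reads = _child_rngs(seed, 3)

    segments: list[np.ndarray] = []
    fam_rows = []
    copy_rows = []
    te_bases = 0
    for spec in specs:
        if spec.id not in lib:
            raise KeyError(f"family {spec.id} missing from library")
        cons = np.frombuffer(lib[spec.id].seq.encode(), dtype=np.uint8)
        cons = np.select([cons == c for c in b"ACGT"], range(4)).astype(np.uint8)
        mixture = spec._mixture()
        ds = [m[0] for m in mixture]
        ws = np.asarray([m[1] for m in mixture], dtype=float)
        ws = ws / ws.sum()
        realized = []
        for ci in range(spec.copy_number):
            d = ds[int(rng_copies.choice(len(ds), p=ws))]
            mutated, rd = _mutate(cons, d, spec.kappa, rng_copies)
            segments.append(mutated)
            te_bases += mutated.size
            realized.append(rd)
            copy_rows.append((spec.id, ci, d, rd))
        fam_rows.append(
            (spec.id, spec.subclass, spec.copy_number, spec.consensus_len,
             spec.copy_number * spec.consensus_len / G,
             float(np.mean(realized)) if realized else np.nan)
        )
    if te_bases > G:
        raise ValueError(f"requested insertions ({te_bases} bp) exceed genome size ({G} bp)")

    bg_total = G - te_bases
    n_chunks = len(segments) + 1
    sizes = rng_bg.multinomial(bg_total, np.full(n_chunks, 1.0 / n_chunks))
    order = rng_bg.permutation(len(segments))
    woven: list[np.ndarray] = [_random_codes(rng_bg, int(sizes[0]))]
    for j, si in enumerate(order):
        woven.append(segments[si])
        woven.append(_random_codes(rng_bg, int(sizes[j + 1])))
    genome = np.concatenate(woven)
    assert genome.size == G

    n_reads = int(round(coverage * G / read_len))
    starts = rng_reads.integers(0, G - read_len + 1, size=n_reads)
    strands = rng_reads.random(n_reads) < 0.5
    windows = genome[starts[:, None] + np.arange(read_len)]
    reads = []
    for i in range(n_reads):
        codes = windows[i]
        if strands[i]:
            codes = (3 - codes)[::-1]
        reads.append(SequenceRecord(f"read{i:07d}", _decode(codes)))

    family_truth = pd.DataFrame(
        fam_rows,
        columns=["family_id", "subclass", "copy_number", "consensus_len",
                 "true_genome_proportion", "mean_realized_divergence"],
    )
    copy_truth = pd.DataFrame(
        copy_rows, columns=["family_id", "copy_index", "divergence", "realized_divergence"]
    )
    return SkimSimulation(reads, family_truth, copy_truth, G, n_reads * read_len)


# ---------------------------------------------------------------------------
# transcriptome


@dataclass
class TranscriptomeSimulation:
    transcripts: list[SequenceRecord]
    domain_hits: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame


def simulate_transcriptome(
    specs: Sequence[TranscriptSpec],
    samples: Sequence[str] | pd.DataFrame,
    seed: int = 0,
    domain_len: int = 300,
) -> TranscriptomeSimulation:
    """Transcript sequences, an ordered domain-hit table, and NB counts.

    ``samples`` is either a list of sample names or a sample sheet with
    columns ``sample`` and ``tissue``; dict-valued ``mean_count`` specs are
    resolved through the tissue column.
    """
    if isinstance(samples, pd.DataFrame):
        sheet = samples
        names = list(sheet["sample"])
    else:
        names = list(samples)
        sheet = pd.DataFrame({"sample": names, "tissue": ["" for _ in names]})
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    transcripts = []
    hit_rows = []
    count_rows = []
    truth_rows = []
    for spec in specs:
        seq = _decode(_random_codes(rng, spec.length))
        transcripts.append(SequenceRecord(spec.id, seq))
        slot = spec.length // len(spec.architecture)
        dl = min(domain_len, max(slot - 20, 10))
        n_dom = len(spec.architecture)
        intervals = []
        for di, dom in enumerate(spec.architecture):
            # on the minus strand the architecture reads along decreasing
            # transcript coordinates
            pos = di if spec.strand == "+" else n_dom - 1 - di
            start = pos * slot + (slot - dl) // 2
            intervals.append((dom, start, start + dl))
        spans = sorted((s, e) for _d, s, e in intervals)
        if any(s < prev_e for (_s0, prev_e), (s, _e) in zip(spans, spans[1:])):
            raise ValueError(f"{spec.id}: overlapping domain intervals")
        for dom, start, end in intervals:
            hit_rows.append((spec.id, dom, spec.clade, start, end, spec.strand))
        means = []
        for _, row in sheet.iterrows():
            if isinstance(spec.mean_count, Mapping):
                means.append(float(spec.mean_count.get(row["tissue"], 0.0)))
            else:
                means.append(float(spec.mean_count))
        counts = []
        for m in means:
            if m <= 0:
                counts.append(0)
            elif spec.dispersion <= 0:
                counts.append(int(rng.poisson(m)))
            else:
                n_param = 1.0 / spec.dispersion
                counts.append(int(rng.negative_binomial(n_param, n_param / (n_param + m))))
        count_rows.append(counts)
        truth_rows.append((spec.id, spec.true_subclass, spec.length,
                           "-".join(spec.architecture), spec.clade))

    domain_hits = pd.DataFrame(
        hit_rows, columns=["transcript_id", "domain", "clade", "start", "end", "strand"]
    )
    counts = pd.DataFrame(count_rows, index=[s.id for s in specs], columns=names)
    counts.index.name = "transcript_id"
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "true_subclass", "length", "architecture", "clade"],
    )
    return TranscriptomeSimulation(transcripts, domain_hits, counts, truth)


# ---------------------------------------------------------------------------
# small RNA


def random_references(prefix: str, n: int, length: int, seed: int) -> list[SequenceRecord]:
    """Random reference sequences (e.g. synthetic rRNA/tRNA or hairpin sets)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [SequenceRecord(f"{prefix}{i}", _decode(_random_codes(rng, length)))
            for i in range(n)]


@dataclass
class SmallRNASimulation:
    reads: list[SequenceRecord]
    truth: pd.DataFrame


def simulate_small_rna(
    spec: SmallRNASpec,
    library: Sequence[TERecord],
    contaminant_refs: Sequence[SequenceRecord],
    hairpin_refs: Sequence[SequenceRecord],
    seed: int = 0,
) -> SmallRNASimulation:
    """A mixed small-RNA pool with a per-read truth table.

    piRNA reads are substrings of a TE consensus (antisense reads are
    reverse complements) with at most one substitution introduced by the
    5'-base rule; miRNAs are exact copies of a hairpin arm; contaminants
    are substrings of the contaminant references; the remainder is random
    sequence ("unannotated").
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = spec.n_reads
    n_pi = int(round(n * spec.pirna_fraction))
    n_mi = int(round(n * spec.mirna_fraction))
    n_ct = int(round(n * spec.contaminant_fraction))
    n_un = n - n_pi - n_mi - n_ct
    if n_un < 0:
        raise ValueError("class fractions sum to more than 1")

    fam_ids = [r.id for r in library]
    lib = {r.id: r for r in library}
    if spec.family_weights is not None:
        unknown = set(spec.family_weights) - set(fam_ids)
        if unknown:
            raise KeyError(f"family_weights reference unknown families: {sorted(unknown)}")
        fam_ids = list(spec.family_weights)
        w = np.asarray([spec.family_weights[f] for f in fam_ids], dtype=float)
    else:
        w = np.ones(len(fam_ids))
    w = w / w.sum()

    len_dist = dict(spec.pirna_len_dist or DEFAULT_PIRNA_LEN_DIST)
    lengths = np.asarray(list(len_dist), dtype=int)
    lprobs = np.asarray([len_dist[int(l)] for l in lengths], dtype=float)
    lprobs = lprobs / lprobs.sum()

    entries: list[tuple[str, str, str | None, str | None]] = []  # seq, class, family, orientation

    if n_pi and not library:
        raise ValueError("piRNAs requested but TE library is empty")
    for _ in range(n_pi):
        fam = fam_ids[int(rng.choice(len(fam_ids), p=w))]
        cons = lib[fam].seq
        L = int(rng.choice(lengths, p=lprobs))
        pos = int(rng.integers(0, len(cons) - L + 1))
        frag = cons[pos : pos + L]
        orientation = "antisense" if rng.random() < spec.antisense_fraction else "sense"
        if orientation == "antisense":
            frag = revcomp(frag)
        if rng.random() < spec.u1_prob:
            first = "T"
        else:
            first = "ACG"[int(rng.integers(0, 3))]
        frag = first + frag[1:]
        entries.append((frag, "piRNA", fam, orientation))

    for _ in range(n_mi):
        hp = hairpin_refs[int(rng.integers(0, len(hairpin_refs)))]
        L = spec.mirna_len
        arm = hp.seq[:L] if rng.random() < 0.5 else hp.seq[-L:]
        entries.append((arm, "miRNA", hp.id, None))

    for _ in range(n_ct):
        ref = contaminant_refs[int(rng.integers(0, len(contaminant_refs)))]
        L = int(rng.integers(18, 32))
        pos = int(rng.integers(0, len(ref.seq) - L + 1))
        entries.append((ref.seq[pos : pos + L], "contaminant", ref.id, None))

    for _ in range(n_un):
        L = int(rng.integers(18, 32))
        entries.append((_decode(_random_codes(rng, L)), "unannotated", None, None))

    order = rng.permutation(len(entries))
    reads = []
    rows = []
    for i, j in enumerate(order):
        seq, klass, source, orientation = entries[j]
        rid = f"sr{i:07d}"
        reads.append(SequenceRecord(rid, seq))
        rows.append((rid, klass, source, orientation, len(seq), seq[0]))
    truth = pd.DataFrame(
        rows, columns=["read_id", "true_class", "source", "orientation", "length", "first_base"]
    )
    return SmallRNASimulation(reads, truth)
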