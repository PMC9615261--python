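"""Sequence and repeat-library records with plain-text I/O.

Coordinates are 0-based half-open in memory.  TSV exports use 1-based
inclusive coordinates; every exported file states this in a ``#`` header
comment so downstream consumers never have to guess the convention.

The repeat-library FASTA dialect follows RepeatMasker: headers are
``id#subclass/superfamily`` where the ``/superfamily`` part is optional.
Subclass labels outside the closed vocabulary (e.g. ``NA``, ``Unknown``)
map to ``unclassified``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "TE_SUBCLASSES",
    "ParseError",
    "SequenceRecord",
    "TERecord",
    "AlignmentHit",
    "revcomp",
    "load_sequences",
    "write_fasta",
    "write_fastq",
    "parse_repeat_library",
    "write_repeat_library",
    "hits_to_frame",
    "write_alignments_tsv",
]

#: Closed vocabulary of repeat subclasses used throughout the pipeline.
TE_SUBCLASSES = (
    "LTR",
    "LINE",
    "SINE",
    "DNA",
    "Helitron",
    "Penelope",
    "rRNA",
    "satellite",
    "unclassified",
)

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised for malformed sequence files; the message names the line."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_seq(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{label}: invalid characters {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    meta: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "seq", _check_seq(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TERecord:
    """A transposable-element consensus sequence with its classification.

    ``subclass`` is drawn from :data:`TE_SUBCLASSES`; ``superfamily`` is
    free text (e.g. ``Ty1_copia``, ``Ty3_gypsy``).  Consensus sequences
    shorter than 50 bp are rejected: below that the skim quantification
    and the divergence bookkeeping are meaningless.
    """

    id: str
    subclass: str = "unclassified"
    superfamily: str | None = None
    seq: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("TE id must be non-empty")
        if self.subclass not in TE_SUBCLASSES:
            raise ValueError(
                f"{self.id}: subclass {self.subclass!r} not in {TE_SUBCLASSES}"
            )
        object.__setattr__(self, "seq", _check_seq(self.seq, self.id))
        if len(self.seq) < 50:
            raise ValueError(f"{self.id}: consensus shorter than 50 bp")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentHit:
    """One ungapped read-to-consensus alignment.

    ``q_start``/``q_end`` are on the read *as oriented to the + strand of
    the target* (i.e. on the reverse complement when ``strand == '-'``).
    Alignment columns where either side is N are excluded from
    ``aligned_len``/``matches``/``transitions``/``transversions``, so
    ``matches + mismatches == aligned_len`` holds exactly.
    """

    query_id: str
    target_id: str
    strand: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    aligned_len: int
    matches: int
    transitions: int
    transversions: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.t_start < self.t_end):
            raise ValueError("target interval must be non-empty and non-negative")
        if self.matches + self.mismatches != self.aligned_len:
            raise ValueError("matches + mismatches must equal aligned_len")

    @property
    def mismatches(self) -> int:
        return self.transitions + self.transversions


# ---------------------------------------------------------------------------
# file I/O


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _iter_fastq(handle: IO[str]) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq, qual) from 4-line FASTQ, raising with line numbers."""
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header:
            continue
        if not header.startswith("@"):
            raise ParseError(f"line {lineno}: FASTQ header must start with '@'")
        block = [handle.readline() for _ in range(3)]
        if any(not ln for ln in block):
            raise ParseError(f"line {lineno + len([b for b in block if b])}: "
                             "truncated FASTQ record")
        seq, plus, qual = (ln.rstrip("\n") for ln in block)
        if not plus.startswith("+"):
            raise ParseError(f"line {lineno + 2}: expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                f"line {lineno + 3}: quality length differs from sequence length"
            )
        lineno += 3
        yield header[1:].split()[0], seq, qual


def load_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read FASTA/FASTQ (gz-transparent) into :class:`SequenceRecord` objects.

    Order is preserved; duplicate ids raise :class:`ParseError`.  FASTQ
    quality strings are parsed (length-checked) and then discarded.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        if format == "fasta":
            try:
                entries = [(r.id, str(r.seq), r.description) for r in SeqIO.parse(handle, "fasta")]
            except ValueError as exc:  # pragma: no cover - Biopython detail
                raise ParseError(f"malformed FASTA in {path}: {exc}") from exc
            for rid, seq, desc in entries:
                meta = desc[len(rid):].strip() if desc.startswith(rid) else desc
                records.append(SequenceRecord(rid, seq, meta))
                if rid in seen:
                    raise ParseError(f"duplicate sequence id {rid!r} in {path}")
                seen.add(rid)
        else:
            for rid, seq, _qual in _iter_fastq(handle):
                records.append(SequenceRecord(rid, seq))
                if rid in seen:
                    raise ParseError(f"duplicate sequence id {rid!r} in {path}")
                seen.add(rid)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.meta}" if rec.meta else "")
            out.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path, qual_char: str = "I") -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.seq}\n+\n{qual_char * len(rec.seq)}\n")


# ---------------------------------------------------------------------------
# repeat-library dialect

_SUBCLASS_ALIASES = {s.lower(): s for s in TE_SUBCLASSES}
_SUBCLASS_ALIASES.update({"na": "unclassified", "unknown": "unclassified"})


def _parse_library_header(header: str) -> tuple[str, str, str | None]:
    name = header.split()[0]
    if "#" not in name:
        return name, "unclassified", None
    rid, _, rest = name.partition("#")
    subclass, _, superfamily = rest.partition("/")
    subclass = _SUBCLASS_ALIASES.get(subclass.lower(), "unclassified")
    return rid, subclass, superfamily or None


def parse_repeat_library(path: str | Path) -> list[TERecord]:
    """Read a RepeatMasker-dialect FASTA library into :class:`TERecord` s."""
    out: list[TERecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rid, subclass, superfamily = _parse_library_header(rec.description or rec.id)
            if rid in seen:
                raise ParseError(f"duplicate library id {rid!r} in {path}")
            seen.add(rid)
            out.append(TERecord(rid, subclass, superfamily, str(rec.seq)))
    return out


def write_repeat_library(records: Iterable[TERecord], path: str | Path) -> None:
    seqs = []
    for r in records:
        name = f"{r.id}#{r.subclass}" + (f"/{r.superfamily}" if r.superfamily else "")
        seqs.append(SequenceRecord(name, r.seq))
    write_fasta(seqs, path)


# ---------------------------------------------------------------------------
# alignment tables

_HIT_COLUMNS = [
    "query_id",
    "target_id",
    "strand",
    "t_start",
    "t_end",
    "aligned_len",
    "mismatches",
    "transitions",
    "transversions",
    "weight",
]


def hits_to_frame(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    """Alignment hits as a DataFrame (0-based half-open, in-memory form)."""
    return pd.DataFrame(
        [
            (
                h.query_id,
                h.target_id,
                h.strand,
                h.t_start,
                h.t_end,
                h.aligned_len,
                h.mismatches,
                h.transitions,
                h.transversions,
                h.weight,
            )
            for h in hits
        ],
        columns=_HIT_COLUMNS,
    )


def write_alignments_tsv(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    """Export hits as TSV with 1-based inclusive target coordinates."""
    frame = hits_to_frame(hits)
    frame["t_start"] = frame["t_start"] + 1  # 1-based inclusive on output
    with open(path, "w") as out:
        out.write("# coordinates: 1-based inclusive (t_start, t_end)\n")
        frame.to_csv(out, sep="\t", index=False)
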