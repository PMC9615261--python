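"""Small-RNA pipeline: from raw reads to TE-derived piRNAs.

The pipeline order is fixed and mirrors common small-RNA practice:

1. adapter trimming and length filtering (retained reads are 18-31 nt);
2. contaminant removal (rRNA/tRNA/snRNA references, end-to-end <= 1
   mismatch) -- a read matching both a contaminant and a TE is a
   contaminant;
3. miRNA identification against hairpin references (<= 1 mismatch);
4. TE-derived piRNA identification: remaining reads of length 23-31 nt
   with at least one best-stratum hit (<= 3 mismatches, all hits
   reported) against TE consensus and TE transcript sequences.

Multi-mapped piRNA reads are split fractionally across their best-stratum
families (total weight 1 per read), so abundance totals are conserved no
matter how the split is arranged.  The 1U statistic is the read-weighted
frequency of T (DNA space) at the 5' first position.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import SmallRNAIndex, map_reads
from .records import SequenceRecord, TERecord

__all__ = [
    "PirnaRecord",
    "PreprocessResult",
    "SmallRNAResult",
    "preprocess_small_rna",
    "remove_contaminants",
    "identify_mirna",
    "identify_te_pirna",
    "base_bias",
    "rpm_normalize",
    "pirna_abundance",
    "run_small_rna_pipeline",
]


@dataclass(frozen=True)
class PirnaRecord:
    """One (read, family) piRNA assignment with fractional weight."""

    read_id: str
    family_id: str
    orientation: str  # sense | antisense
    weight: float
    first_base: str

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must lie in (0, 1]")


@dataclass
class PreprocessResult:
    retained: list[SequenceRecord]
    length_hist: pd.Series
    n_input: int
    n_too_short: int
    n_too_long: int


def _trim_adapter(seq: str, adapter: str) -> str:
    key = adapter[:10]
    idx = seq.find(key)
    if idx >= 0:
        return seq[:idx]
    # 3' end may carry only the start of the adapter: full-suffix overlap >= 5
    for k in range(min(len(seq), 9), 4, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k]
    return seq


def preprocess_small_rna(
    reads: Sequence[SequenceRecord],
    adapter: str | None = None,
    min_len: int = 18,
    max_len: int = 31,
) -> PreprocessResult:
    """Trim 3' adapters and keep reads of ``min_len``..``max_len`` nt.

    Trimming cuts at the leftmost exact match of the adapter's first
    10 nt; failing that, a terminal overlap of >= 5 nt with the adapter
    prefix is removed.  Pre-trimmed input (``adapter=None``) passes
    straight to the length filter.
    """
    if adapter is not None and len(adapter) < 10:
        raise ValueError("adapter must be at least 10 nt")
    retained = []
    too_short = too_long = 0
    for read in reads:
        seq = _trim_adapter(read.seq, adapter) if adapter else read.seq
        if len(seq) < min_len:
            too_short += 1
        elif len(seq) > max_len:
            too_long += 1
        else:
            retained.append(SequenceRecord(read.id, seq))
    lengths = pd.Series([len(r.seq) for r in retained], dtype=int)
    hist = lengths.value_counts().sort_index()
    hist.index.name = "length"
    return PreprocessResult(retained, hist, len(reads), too_short, too_long)


def _mapped_ids(reads: Sequence[SequenceRecord], refs: Sequence[SequenceRecord],
                max_mismatch: int) -> set[str]:
    hits = map_reads(reads, refs, "smallrna", max_mismatch=max_mismatch)
    return {h.query_id for h in hits}


def remove_contaminants(
    reads: Sequence[SequenceRecord],
    refs: Sequence[SequenceRecord],
    max_mismatch: int = 1,
) -> tuple[list[SequenceRecord], float]:
    """Drop reads mapping end-to-end (<= ``max_mismatch``) to any reference."""
    if not refs:
        warnings.warn("no contaminant references supplied; skipping removal", stacklevel=2)
        return list(reads), 0.0
    removed = _mapped_ids(reads, refs, max_mismatch)
    kept = [r for r in reads if r.id not in removed]
    return kept, len(removed) / len(reads) if reads else 0.0


def identify_mirna(
    reads: Sequence[SequenceRecord],
    hairpins: Sequence[SequenceRecord],
    max_mismatch: int = 1,
) -> tuple[list[SequenceRecord], list[SequenceRecord], float]:
    """Split reads into (miRNA, remainder) by hairpin mapping."""
    if not hairpins:
        return [], list(reads), 0.0
    ids = _mapped_ids(reads, hairpins, max_mismatch)
    mirna = [r for r in reads if r.id in ids]
    rest = [r for r in reads if r.id not in ids]
    return mirna, rest, len(mirna) / len(reads) if reads else 0.0


def identify_te_pirna(
    reads: Sequence[SequenceRecord],
    te_refs: Sequence[TERecord | SequenceRecord],
    max_mismatch: int = 3,
    min_len: int = 23,
    max_len: int = 31,
    target_to_family: Mapping[str, str] | None = None,
) -> list[PirnaRecord]:
    """TE-derived piRNAs: 23-31 nt reads with a best-stratum TE hit.

    ``te_refs`` is the union of TE consensus and TE transcript sequences;
    ``target_to_family`` collapses transcript ids onto their family
    (identity by default).  Hits are deduplicated per read-family pair and
    the read's unit weight is split evenly across its families.
    Orientation is sense when the read maps to the + strand of the
    reference (references are stored 5'->3' in sense orientation).
    """
    if not te_refs:
        raise ValueError("te_refs must be non-empty")
    eligible = [r for r in reads if min_len <= len(r.seq) <= max_len]
    if not eligible:
        return []
    hits = map_reads(eligible, te_refs, "smallrna", max_mismatch=max_mismatch)
    fam = target_to_family or {}
    per_read: dict[str, dict[str, tuple[int, str]]] = defaultdict(dict)
    for h in hits:
        family = fam.get(h.target_id, h.target_id)
        orientation = "sense" if h.strand == "+" else "antisense"
        prev = per_read[h.query_id].get(family)
        cand = (h.mismatches, orientation)
        # keep the lowest-mismatch placement; sense wins ties
        if prev is None or cand < prev:
            per_read[h.query_id][family] = cand
    seqs = {r.id: r.seq for r in eligible}
    records = []
    for rid, families in per_read.items():
        w = 1.0 / len(families)
        for family, (_mm, orientation) in sorted(families.items()):
            records.append(PirnaRecord(rid, family, orientation, w, seqs[rid][0]))
    return records


def base_bias(
    pirnas: Sequence[PirnaRecord],
    reads: Sequence[SequenceRecord],
) -> tuple[pd.DataFrame, float]:
    """Positional nucleotide frequencies of piRNA reads and the 1U fraction.

    Read-weighted: every piRNA read counts once regardless of how its
    mapping weight is split.  Rows are positions 1..31; each populated row
    sums to 1.  The 1U fraction is the frequency of T at position 1.
    """
    if not pirnas:
        raise ValueError("empty piRNA set")
    seqs = {r.id: r.seq for r in reads}
    read_ids = sorted({p.read_id for p in pirnas})
    max_pos = max(len(seqs[rid]) for rid in read_ids)
    counts = pd.DataFrame(0.0, index=range(1, max_pos + 1), columns=list("ACGT"))
    for rid in read_ids:
        for pos, base in enumerate(seqs[rid], start=1):
            if base in counts.columns:
                counts.loc[pos, base] += 1.0
    totals = counts.sum(axis=1)
    freq = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    freq.index.name = "position"
    u1 = float(freq.loc[1, "T"])
    return freq, u1


def rpm_normalize(counts: pd.Series | Mapping[str, float], denominator: int) -> pd.Series:
    """Reads-per-million: weighted counts / denominator * 1e6."""
    if denominator <= 0:
        raise ValueError("RPM denominator must be positive")
    series = pd.Series(counts, dtype=float)
    return series / denominator * 1e6


def pirna_abundance(pirnas: Sequence[PirnaRecord], denominator: int,
                    families: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-family weighted piRNA counts and RPM, split by orientation.

    ``families`` forces rows (with zeros) for families without piRNAs.
    """
    sense: dict[str, float] = defaultdict(float)
    anti: dict[str, float] = defaultdict(float)
    for p in pirnas:
        if p.orientation == "sense":
            sense[p.family_id] += p.weight
        else:
            anti[p.family_id] += p.weight
    index = sorted(set(sense) | set(anti) | set(families or []))
    frame = pd.DataFrame(
        {
            "sense_reads": [sense.get(f, 0.0) for f in index],
            "antisense_reads": [anti.get(f, 0.0) for f in index],
        },
        index=pd.Index(index, name="family_id"),
    )
    frame["total_reads"] = frame["sense_reads"] + frame["antisense_reads"]
    for col in ("sense", "antisense", "total"):
        frame[f"{col}_rpm"] = rpm_normalize(frame[f"{col}_reads"], denominator)
    return frame


@dataclass
class SmallRNAResult:
    """Everything the small-RNA stage reports."""

    classes: pd.DataFrame          # read_id, length, class
    fractions: dict[str, float]    # class -> fraction of retained reads
    pirnas: list[PirnaRecord]
    length_hist: pd.Series
    base_bias: pd.DataFrame
    u1_fraction: float
    abundance: pd.DataFrame
    rpm_denominator: int

    def write(self, outdir) -> None:
        """Dump the stage outputs as TSV plus a JSON summary."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.classes.to_csv(outdir / "classes.tsv", sep="\t", index=False)
        self.length_hist.rename("count").to_csv(outdir / "length_hist.tsv", sep="\t")
        self.base_bias.to_csv(outdir / "base_bias.tsv", sep="\t")
        self.abundance.to_csv(outdir / "pirna_abundance.tsv", sep="\t")
        summary = {
            "fractions": self.fractions,
            "u1_fraction": self.u1_fraction,
            "rpm_denominator": self.rpm_denominator,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def run_small_rna_pipeline(
    reads: Sequence[SequenceRecord],
    te_refs: Sequence[TERecord | SequenceRecord],
    contaminant_refs: Sequence[SequenceRecord] = (),
    hairpin_refs: Sequence[SequenceRecord] = (),
    adapter: str | None = None,
    max_mismatch: int = 3,
    min_len: int = 18,
    max_len: int = 31,
    pirna_min: int = 23,
    pirna_max: int = 31,
    target_to_family: Mapping[str, str] | None = None,
    rpm_denominator: str = "retained",
) -> SmallRNAResult:
    """Run the full pipeline: trim -> contaminants -> miRNA -> piRNA.

    ``rpm_denominator`` selects the RPM library size: ``"retained"``
    (reads surviving the length filter, the default) or ``"clean"``
    (reads surviving contaminant removal).
    """
    prep = preprocess_small_rna(reads, adapter, min_len, max_len)
    kept, _contam_frac = remove_contaminants(prep.retained, list(contaminant_refs))
    mirna, rest, _mirna_frac = identify_mirna(kept, list(hairpin_refs))
    pirnas = identify_te_pirna(rest, te_refs, max_mismatch, pirna_min, pirna_max,
                               target_to_family)
    pirna_ids = {p.read_id for p in pirnas}

    kept_ids = {k.id for k in kept}
    klass = {}
    for r in prep.retained:
        klass[r.id] = "unannotated" if r.id in kept_ids else "contaminant"
    for r in mirna:
        klass[r.id] = "miRNA"
    for rid in pirna_ids:
        klass[rid] = "piRNA"
    classes = pd.DataFrame(
        {
            "read_id": [r.id for r in prep.retained],
            "length": [len(r.seq) for r in prep.retained],
            "class": [klass[r.id] for r in prep.retained],
        }
    )
    n_retained = len(prep.retained)
    fractions = (
        classes["class"].value_counts(normalize=True).reindex(
            ["contaminant", "miRNA", "piRNA", "unannotated"], fill_value=0.0
        ).to_dict()
        if n_retained
        else {}
    )
    denominator = n_retained if rpm_denominator == "retained" else len(kept)
    fam_map = target_to_family or {}
    family_rows = sorted({fam_map.get(r.id, r.id) for r in te_refs})
    if pirnas:
        bias, u1 = base_bias(pirnas, prep.retained)
        abundance = pirna_abundance(pirnas, denominator, families=family_rows)
    else:
        bias, u1 = pd.DataFrame(columns=list("ACGT")), float("nan")
        abundance = pirna_abundance([], denominator, families=family_rows)
    return SmallRNAResult(classes, fractions, pirnas, prep.length_hist,
                          bias, u1, abundance, denominator)
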