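"""Genome-skim repeat quantification and K2P divergence landscapes.

The quantities computed here are the standard descriptors of a repeatome
from low-coverage reads:

* per-family genome proportion ``g_f`` = aligned bases / total sampled
  bases, and the skim copy-number estimator ``N = g * G / L`` (genome
  proportion times genome size over consensus length);
* the divergence landscape: genome fraction binned by the Kimura
  2-parameter distance of each read-to-consensus alignment, per subclass;
* cross-species shared families by reciprocal best consensus match
  (default "80/80": >= 80% identity over >= 80% of the shorter consensus);
* per-position consensus coverage profiles, scaled per sampled Gbp so two
  skims of different depth are comparable.

The Kimura 2-parameter distance corrects transitions (P) and transversions
(Q) separately: ``K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import GenomicIndex, map_reads
from .records import AlignmentHit, SequenceRecord, TERecord

__all__ = [
    "K2PSaturationError",
    "k2p_distance",
    "quantify_repeats",
    "estimate_copy_number",
    "add_copy_number_estimates",
    "LandscapeResult",
    "build_landscape",
    "SharedFamilyRecord",
    "find_shared_families",
    "CoverageProfile",
    "coverage_profile",
]


class K2PSaturationError(ValueError):
    """The (P, Q) pair lies outside the domain of the K2P distance."""


def k2p_distance(P: float, Q: float) -> float:
    """Kimura 2-parameter distance in substitutions per site.

    Raises :class:`K2PSaturationError` when ``1 - 2P - Q <= 0`` or
    ``1 - 2Q <= 0`` (the distance is undefined; such alignments are
    tallied separately by :func:`build_landscape`).
    """
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValueError(f"invalid substitution fractions P={P}, Q={Q}")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise K2PSaturationError(f"K2P undefined for P={P}, Q={Q}")
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 avoids IEEE -0.0


def _hit_k2p_percent(hit: AlignmentHit) -> float:
    P = hit.transitions / hit.aligned_len
    Q = hit.transversions / hit.aligned_len
    return 100.0 * k2p_distance(P, Q)


def quantify_repeats(
    hits: Sequence[AlignmentHit],
    reads: Sequence[SequenceRecord],
    library: Sequence[TERecord],
    genome_size_bp: int | None = None,
) -> pd.DataFrame:
    """Per-family aligned bases and genome proportion from genomic-mode hits.

    Every library family appears (zero rows included); rows are sorted by
    genome proportion, descending.  When ``genome_size_bp`` is given a
    ``copy_number_est`` column is added.
    """
    if not reads:
        raise ValueError("empty read set")
    total = sum(len(r.seq) for r in reads)
    aligned: dict[str, float] = {r.id: 0.0 for r in library}
    for h in hits:
        if h.target_id not in aligned:
            raise KeyError(f"hit targets unknown family {h.target_id}")
        aligned[h.target_id] += h.aligned_len * h.weight
    meta = {r.id: r for r in library}
    frame = pd.DataFrame(
        {
            "family_id": list(aligned),
            "subclass": [meta[f].subclass for f in aligned],
            "aligned_bases": [aligned[f] for f in aligned],
        }
    )
    frame["genome_proportion"] = frame["aligned_bases"] / total
    if genome_size_bp is not None:
        frame = add_copy_number_estimates(frame, library, genome_size_bp)
    return frame.sort_values("genome_proportion", ascending=False, ignore_index=True)


def estimate_copy_number(genome_proportion: float, consensus_len: int,
                         genome_size_bp: int) -> int:
    """Skim copy-number estimator ``N = g * G / L``, rounded to integer."""
    if consensus_len <= 0:
        raise ValueError("consensus_len must be positive")
    return int(round(genome_proportion * genome_size_bp / consensus_len))


def add_copy_number_estimates(quant: pd.DataFrame, library: Sequence[TERecord],
                              genome_size_bp: int) -> pd.DataFrame:
    lens = {r.id: len(r.seq) for r in library}
    quant = quant.copy()
    quant["copy_number_est"] = [
        estimate_copy_number(g, lens[f], genome_size_bp)
        for f, g in zip(quant["family_id"], quant["genome_proportion"])
    ]
    return quant


@dataclass
class LandscapeResult:
    """Divergence landscape: genome fraction per (subclass, K2P-percent bin).

    ``table`` has columns subclass, bin_lo, bin_hi, genome_fraction over
    the full grid [0, max_percent) in ``bin_width`` steps.
    ``excluded_fraction`` is the mass of alignments whose distance
    saturated or fell outside the grid; together the two conserve the
    total aligned genome proportion exactly.
    """

    table: pd.DataFrame
    excluded_fraction: float
    bin_width: float
    max_percent: float

    def total_by_bin(self) -> pd.Series:
        return self.table.groupby("bin_lo", sort=True)["genome_fraction"].sum()

    def modal_bin(self, subclass: str | None = None) -> tuple[float, float]:
        """(bin_lo, bin_hi) of the most massive bin, optionally per subclass."""
        tab = self.table
        if subclass is not None:
            tab = tab[tab["subclass"] == subclass]
        row = tab.loc[tab["genome_fraction"].idxmax()]
        return float(row["bin_lo"]), float(row["bin_hi"])


def build_landscape(
    hits: Sequence[AlignmentHit],
    reads: Sequence[SequenceRecord],
    library: Sequence[TERecord],
    bin_width: float = 1.0,
    max_percent: float = 35.0,
) -> LandscapeResult:
    """Bin genomic-mode hits by K2P distance into a divergence landscape.

    Each hit contributes ``aligned_len * weight / total sampled bases`` to
    the bin of its K2P percent within its family's subclass.
    """
    if not reads:
        raise ValueError("empty read set")
    total = sum(len(r.seq) for r in reads)
    subclass_of = {r.id: r.subclass for r in library}
    nbins = int(round(max_percent / bin_width))
    subclasses = sorted({r.subclass for r in library})
    grid = {s: np.zeros(nbins) for s in subclasses}
    excluded = 0.0
    for h in hits:
        mass = h.aligned_len * h.weight / total
        try:
            pct = _hit_k2p_percent(h)
        except K2PSaturationError:
            excluded += mass
            continue
        b = int(pct // bin_width)
        if b >= nbins:
            excluded += mass
            continue
        grid[subclass_of[h.target_id]][b] += mass
    rows = [
        (s, i * bin_width, (i + 1) * bin_width, grid[s][i])
        for s in subclasses
        for i in range(nbins)
    ]
    table = pd.DataFrame(rows, columns=["subclass", "bin_lo", "bin_hi", "genome_fraction"])
    return LandscapeResult(table, excluded, bin_width, max_percent)


@dataclass(frozen=True)
class SharedFamilyRecord:
    family_id: str
    partner_id: str
    copy_number_a: int
    copy_number_b: int
    identity_percent: float


def _best_consensus_match(rec: TERecord, index: GenomicIndex,
                          min_identity: float, min_coverage: float) -> tuple[str, float] | None:
    query = SequenceRecord(rec.id, rec.seq)
    hits = map_reads([query], index.records, "genomic", index=index)  # type: ignore[arg-type]
    if not hits:
        return None
    hit = hits[0]
    target_len = next(len(r.seq) for r in index.records if r.id == hit.target_id)
    identity = hit.matches / hit.aligned_len
    coverage = hit.aligned_len / min(len(rec.seq), target_len)
    if identity >= min_identity and coverage >= min_coverage:
        return hit.target_id, 100.0 * identity
    return None


def find_shared_families(
    library_a: Sequence[TERecord],
    library_b: Sequence[TERecord],
    quant_a: pd.DataFrame,
    quant_b: pd.DataFrame,
    min_copies: int = 500,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
) -> list[SharedFamilyRecord]:
    """Families shared between two species' libraries.

    A pair is shared when the consensus sequences are reciprocal best
    matches at >= ``min_identity`` over >= ``min_coverage`` of the shorter
    consensus, and both skim copy-number estimates exceed ``min_copies``.
    ``quant_a``/``quant_b`` must carry a ``copy_number_est`` column (see
    :func:`quantify_repeats` with ``genome_size_bp``).
    """
    if not library_a or not library_b:
        raise ValueError("both libraries must be non-empty")
    copies_a = dict(zip(quant_a["family_id"], quant_a["copy_number_est"]))
    copies_b = dict(zip(quant_b["family_id"], quant_b["copy_number_est"]))
    idx_a = GenomicIndex(library_a, 12)
    idx_b = GenomicIndex(library_b, 12)
    best_ab = {
        rec.id: _best_consensus_match(rec, idx_b, min_identity, min_coverage)
        for rec in library_a
    }
    best_ba = {
        rec.id: _best_consensus_match(rec, idx_a, min_identity, min_coverage)
        for rec in library_b
    }
    shared = []
    for rec in library_a:
        match = best_ab[rec.id]
        if match is None:
            continue
        partner, identity = match
        back = best_ba.get(partner)
        if back is None or back[0] != rec.id:
            continue
        ca = int(copies_a.get(rec.id, 0))
        cb = int(copies_b.get(partner, 0))
        if ca > min_copies and cb > min_copies:
            shared.append(SharedFamilyRecord(rec.id, partner, ca, cb, identity))
    return shared


@dataclass
class CoverageProfile:
    """Per-consensus-position read depth, raw and per sampled Gbp."""

    family_id: str
    depth: np.ndarray
    scaled_depth: np.ndarray


def coverage_profile(
    hits: Sequence[AlignmentHit],
    family_id: str,
    library: Sequence[TERecord],
    total_read_bases: int,
) -> CoverageProfile:
    """Stacked hit intervals along one family's consensus.

    ``scaled_depth`` divides by the total sampled bases in Gbp, making
    profiles from skims of different depth directly comparable.
    """
    lens = {r.id: len(r.seq) for r in library}
    if family_id not in lens:
        raise KeyError(f"unknown family {family_id!r}")
    diff = np.zeros(lens[family_id] + 1)
    for h in hits:
        if h.target_id != family_id:
            continue
        diff[h.t_start] += h.weight
        diff[h.t_end] -= h.weight
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(family_id, depth, depth / (total_read_bases / 1e9))
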