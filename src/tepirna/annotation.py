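"""Retrotransposon transcript classification and expression normalization.

Transcripts are classified from their ordered protein-domain hits
(GAG, PROT, INT, RT, RH).  LTR calls require all three of INT, RT and RH:
integrase upstream of RT is the Ty1_copia arrangement
(GAG-PROT-INT-RT-RH), integrase downstream of RH is Ty3_gypsy
(GAG-PROT-RT-RH-INT); GAG and PROT corroborate but are not required.
Without the full INT/RT/RH triplet, a transcript with an RT domain is
assigned by the RT clade label (LINE or Penelope); anything else is
unclassified.  Classification is invariant to a global strand flip of the
hits: the majority strand decides the reading orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DOMAINS",
    "PIRNA_PATHWAY_GENES",
    "DomainHit",
    "TranscriptAnnotation",
    "classify_domain_architecture",
    "annotate_transcripts",
    "tpm_normalize",
    "compare_groups",
    "extract_pathway_genes",
]

DOMAINS = ("GAG", "PROT", "INT", "RT", "RH")
RT_CLADES = ("LINE", "Penelope", "Ty1", "Ty3")

#: Canonical piRNA-pathway (Ping-Pong cycle) genes tracked by the pipeline.
PIRNA_PATHWAY_GENES = ("HENMT", "AGO3", "PIWI2", "PIWI3")


@dataclass(frozen=True)
class DomainHit:
    transcript_id: str
    domain: str
    clade: str | None
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.end <= self.start:
            raise ValueError("domain interval must be non-empty")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class TranscriptAnnotation:
    transcript_id: str
    assigned_class: str
    evidence: str


def _as_hits(hits: Iterable[DomainHit] | pd.DataFrame) -> list[DomainHit]:
    if isinstance(hits, pd.DataFrame):
        return [
            DomainHit(r.transcript_id, r.domain,
                      None if pd.isna(r.clade) else r.clade,
                      int(r.start), int(r.end), r.strand)
            for r in hits.itertuples(index=False)
        ]
    return list(hits)


def classify_domain_architecture(
    hits: Iterable[DomainHit] | pd.DataFrame,
) -> TranscriptAnnotation:
    """Assign a retrotransposon class from one transcript's domain hits."""
    hitlist = _as_hits(hits)
    if not hitlist:
        raise ValueError("no domain hits supplied")
    tids = {h.transcript_id for h in hitlist}
    if len(tids) != 1:
        raise ValueError(f"hits span several transcripts: {sorted(tids)}")
    tid = hitlist[0].transcript_id

    n_minus = sum(1 for h in hitlist if h.strand == "-")
    reverse = n_minus > len(hitlist) - n_minus
    ordered = sorted(hitlist, key=lambda h: h.start, reverse=reverse)
    evidence = "-".join(h.domain for h in ordered)
    domains = [h.domain for h in ordered]

    clades = {h.clade for h in hitlist if h.clade is not None}
    if len(clades) > 1:
        warnings.warn(
            f"{tid}: conflicting clade labels {sorted(clades)}; left unclassified",
            stacklevel=2,
        )
        return TranscriptAnnotation(tid, "unclassified", evidence)
    clade = next(iter(clades)) if clades else None

    if {"INT", "RT", "RH"} <= set(domains):
        i_int = domains.index("INT")
        i_rt = domains.index("RT")
        i_rh = domains.index("RH")
        if i_int < i_rt:
            assigned = "LTR/Ty1_copia"
        elif i_int > i_rh:
            assigned = "LTR/Ty3_gypsy"
        else:
            assigned = "unclassified"
    elif "RT" in domains and clade == "LINE":
        assigned = "LINE"
    elif "RT" in domains and clade == "Penelope":
        assigned = "Penelope"
    else:
        assigned = "unclassified"
    return TranscriptAnnotation(tid, assigned, evidence)


def annotate_transcripts(domain_hits: pd.DataFrame) -> pd.DataFrame:
    """Classify every transcript in a domain-hit table.

    Returns a frame with columns transcript_id, assigned_class, evidence.
    """
    rows = []
    for tid, group in domain_hits.groupby("transcript_id", sort=True):
        ann = classify_domain_architecture(group)
        rows.append((tid, ann.assigned_class, ann.evidence))
    return pd.DataFrame(rows, columns=["transcript_id", "assigned_class", "evidence"])


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series | Mapping[str, float]) -> pd.DataFrame:
    """Transcripts-per-million over the *full* transcriptome.

    ``TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6`` per sample.  Columns
    of an all-zero sample stay zero and trigger a warning.  The
    normalization must run before any feature subsetting, otherwise the
    columns no longer sum to 1e6.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"missing lengths for {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("all transcript lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"all-zero samples: {list(denom.index[zero])}", stacklevel=2)
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def compare_groups(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    feature_sets: Mapping[str, Sequence[str]] | Sequence[str] | None = None,
    aggregate: str = "sum",
    log_scale: bool = False,
) -> pd.DataFrame:
    """Welch two-sided t-tests between two sample groups.

    ``feature_sets`` may be a mapping class -> features (one test per
    class on the per-sample aggregate over the class's features, sum by
    default) or a plain feature list (one test per feature).  With
    ``log_scale`` the test runs on log2(x + 1).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if feature_sets is None:
        feature_sets = list(matrix.index)
    if not isinstance(feature_sets, Mapping):
        feature_sets = {f: [f] for f in feature_sets}
    agg = {"sum": np.sum, "mean": np.mean}[aggregate]
    rows = []
    for name, feats in feature_sets.items():
        sub = matrix.loc[list(feats)]
        xa = np.asarray([agg(sub[s].to_numpy()) for s in group_a], dtype=float)
        xb = np.asarray([agg(sub[s].to_numpy()) for s in group_b], dtype=float)
        if log_scale:
            xa, xb = np.log2(xa + 1), np.log2(xb + 1)
        if np.var(xa) == 0 and np.var(xb) == 0 and xa.mean() == xb.mean():
            t, p, dof = 0.0, 1.0, float(len(xa) + len(xb) - 2)
        else:
            res = stats.ttest_ind(xa, xb, equal_var=False)
            t, p, dof = float(res.statistic), float(res.pvalue), float(res.df)
        rows.append((name, len(xa), len(xb), xa.mean(), xb.mean(), t, dof, p))
    return pd.DataFrame(
        rows, columns=["feature", "n_a", "n_b", "mean_a", "mean_b", "t", "df", "p"]
    )


def extract_pathway_genes(
    matrix: pd.DataFrame,
    annotation_map: Mapping[str, str],
    genes: Sequence[str] = PIRNA_PATHWAY_GENES,
) -> pd.DataFrame:
    """Gene-level expression for the piRNA-pathway genes.

    ``annotation_map`` maps transcript id -> gene symbol.  Each gene row is
    the sum of its transcripts' values; a gene with no mapped transcript
    yields a zero row plus a warning.  Unknown transcript ids are an error.
    """
    if not annotation_map:
        warnings.warn("empty annotation map: no pathway genes extracted", stacklevel=2)
        return pd.DataFrame(columns=matrix.columns)
    unknown = [t for t in annotation_map if t not in matrix.index]
    if unknown:
        raise KeyError(f"annotation map names unknown transcripts: {unknown[:5]}")
    out = pd.DataFrame(0.0, index=list(genes), columns=matrix.columns)
    for tid, gene in annotation_map.items():
        if gene not in out.index:
            out.loc[gene] = 0.0
        out.loc[gene] += matrix.loc[tid]
    empty = [g for g in genes if g not in set(annotation_map.values())]
    if empty:
        warnings.warn(f"no transcripts mapped for genes: {empty}", stacklevel=2)
    return out
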