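"""Correlation and linear-fit analyses linking TE transcripts to piRNAs.

The central question these statistics address: in a host with an intact
piRNA response, TE-derived piRNA abundance (RPM) tracks TE transcript
abundance (TPM) family by family -- a positive Pearson correlation per
retrotransposon class; when silencing is impaired the correlation
collapses.  Correlations run on untransformed axes, per class and per
orientation (sense / antisense / total), with the p-value from the exact
t-transform ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` against t(n - 2).
Classes with fewer than 3 families are skipped (no meaningful r).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "pearson_with_p",
    "linear_fit",
    "build_te_pirna_table",
    "correlate_by_class",
    "correlate_k2p_abundance",
]


@dataclass(frozen=True)
class CorrelationResult:
    label: str
    orientation: str
    n: int
    r: float
    p: float
    slope: float
    intercept: float


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the two-sided t-test p-value.

    Requires n >= 3 and positive variance on both axes; a zero-variance
    input is an error rather than a silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return r, p


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least squares y = slope * x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.var(x) == 0:
        raise ValueError("zero x-variance: slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept)


def build_te_pirna_table(
    te_tpm: pd.Series | Mapping[str, float],
    abundance: pd.DataFrame,
    classes: pd.Series | Mapping[str, str],
    k2p_percent: pd.Series | Mapping[str, float] | None = None,
    tpm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Join transcript TPM with per-family piRNA RPM.

    One row per family with TPM above ``tpm_threshold`` (the expressed
    set); families without piRNAs keep a zero-RPM row.  ``abundance`` is
    the frame from :func:`tepirna.smallrna.pirna_abundance`.
    """
    te_tpm = pd.Series(te_tpm, dtype=float)
    classes = pd.Series(classes)
    missing = [f for f in te_tpm.index if f not in classes.index]
    if missing:
        raise KeyError(f"families without class annotation: {missing[:5]}")
    expressed = te_tpm[te_tpm > tpm_threshold]
    rows = []
    for fam, tpm in expressed.items():
        if fam in abundance.index:
            ab = abundance.loc[fam]
            sense, anti = float(ab["sense_rpm"]), float(ab["antisense_rpm"])
        else:
            sense = anti = 0.0
        k2p = None
        if k2p_percent is not None:
            k2p = float(pd.Series(k2p_percent).get(fam, np.nan))
        rows.append((fam, classes[fam], float(tpm), sense, anti, sense + anti, k2p))
    return pd.DataFrame(
        rows,
        columns=["family_id", "class", "te_tpm", "sense_rpm",
                 "antisense_rpm", "total_rpm", "k2p_percent"],
    )


def correlate_by_class(
    table: pd.DataFrame,
    orientations: Sequence[str] = ("sense", "antisense", "total"),
    min_n: int = 3,
    pooled_label: str = "all",
) -> list[CorrelationResult]:
    """Pearson r, p and OLS fit of piRNA RPM vs transcript TPM.

    One result per (class, orientation) with n >= ``min_n``, plus pooled
    rows across all classes under ``pooled_label``.
    """
    results = []
    groups = [(pooled_label, table)] + [
        (str(c), g) for c, g in table.groupby("class", sort=True)
    ]
    for label, group in groups:
        if len(group) < min_n:
            continue
        for orient in orientations:
            x = group["te_tpm"].to_numpy()
            y = group[f"{orient}_rpm"].to_numpy()
            if np.var(x) == 0 or np.var(y) == 0:
                continue
            r, p = pearson_with_p(x, y)
            slope, intercept = linear_fit(x, y)
            results.append(CorrelationResult(label, orient, len(group), r, p,
                                             slope, intercept))
    return results


def correlate_k2p_abundance(
    k2p_percent: pd.Series | Mapping[str, float],
    abundance: pd.Series | Mapping[str, float],
) -> CorrelationResult:
    """Pearson correlation of per-family K2P divergence with an abundance.

    ``abundance`` may be copy number or piRNA RPM; families are matched by
    index.
    """
    k2p = pd.Series(k2p_percent, dtype=float)
    ab = pd.Series(abundance, dtype=float)
    common = k2p.index.intersection(ab.index)
    x = k2p[common].to_numpy()
    y = ab[common].to_numpy()
    r, p = pearson_with_p(x, y)
    slope, intercept = linear_fit(x, y)
    return CorrelationResult("k2p", "total", len(common), r, p, slope, intercept)
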