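"""Three-tier expression QC: log2 transform, entropy filter, connectivity filter.

RNA abundance matrices mix highly skewed, low-information transcripts with
the coherently varying ones that carry network signal. The filter cascade
applied here is

1. power (log2) transformation, compressing the dynamic range;
2. Shannon-Weiner entropy filtering, dropping transcripts whose
   expression occupies few histogram bins (low informational variability);
3. soft-connectivity filtering, dropping transcripts weakly correlated
   with the rest of the transcriptome (low network degree).

Stage order is fixed (transform -> entropy -> connectivity) and each stage
returns a subset of the previous gene set, with counts tracked in a
:class:`QcReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "QcReport",
    "log2_transform",
    "transcript_entropy",
    "entropy_filter",
    "soft_connectivity",
    "connectivity_filter",
    "run_qc",
]

DEFAULT_ENTROPY_BITS = 3.97   # entropy threshold, bits
DEFAULT_K_MIN = 45.0          # soft-connectivity (degree) threshold
DEFAULT_N_BINS = 16
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class QcReport:
    """Bookkeeping for one pass through the QC cascade."""

    n_input_genes: int = 0
    n_after_entropy: int = 0
    n_after_connectivity: int = 0
    mean_before: float = np.nan
    sd_before: float = np.nan
    mean_after: float = np.nan
    sd_after: float = np.nan
    entropy_bits: pd.Series = field(default_factory=pd.Series)
    connectivity: pd.Series = field(default_factory=pd.Series)

    def summary(self) -> str:
        return (
            f"QC: {self.n_input_genes} genes in -> "
            f"{self.n_after_entropy} after entropy -> "
            f"{self.n_after_connectivity} after connectivity; "
            f"transform mean/sd {self.mean_before:.4g}/{self.sd_before:.4g} -> "
            f"{self.mean_after:.4g}/{self.sd_after:.4g}"
        )


def log2_transform(
    X: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    report: QcReport | None = None,
) -> ExpressionMatrix:
    """v -> log2(v + pseudocount), elementwise.

    Refuses already-transformed input (a double transform silently
    destroys the abundance scale).
    """
    if X.transformed:
        raise ValueError("matrix is already log2-transformed")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    vals = X.values.to_numpy()
    out = np.log2(vals + pseudocount)
    if report is not None:
        report.mean_before = float(vals.mean())
        report.sd_before = float(vals.std())
        report.mean_after = float(out.mean())
        report.sd_after = float(out.std())
    return ExpressionMatrix(
        pd.DataFrame(out, index=X.gene_ids, columns=X.sample_ids), transformed=True
    )


def transcript_entropy(x, n_bins: int = DEFAULT_N_BINS) -> float:
    """Shannon-Weiner entropy (bits) of one transcript's expression profile.

    Samples are binned into ``n_bins`` equal-width bins spanning
    [min(x), max(x)]; H = -sum p_i log2 p_i over occupied bins. A constant
    profile occupies a single bin and scores 0 bits.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("entropy input must be finite")
    if x.max() == x.min():
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def _entropy_per_gene(X: ExpressionMatrix, n_bins: int) -> pd.Series:
    vals = X.values.to_numpy()
    h = np.fromiter(
        (transcript_entropy(row, n_bins) for row in vals), dtype=float, count=len(vals)
    )
    return pd.Series(h, index=X.gene_ids, name="entropy_bits")


def entropy_filter(
    X: ExpressionMatrix,
    threshold_bits: float = DEFAULT_ENTROPY_BITS,
    n_bins: int = DEFAULT_N_BINS,
    report: QcReport | None = None,
) -> ExpressionMatrix:
    """Retain genes with entropy >= threshold_bits (inclusive)."""
    if not X.transformed:
        raise ValueError("entropy filter expects a log2-transformed matrix")
    if threshold_bits > np.log2(n_bins):
        warnings.warn(
            f"entropy threshold {threshold_bits} bits exceeds the "
            f"log2(n_bins) = {np.log2(n_bins):.3g}-bit ceiling: no gene can pass",
            stacklevel=2,
        )
    h = _entropy_per_gene(X, n_bins)
    keep = h.index[h >= threshold_bits]
    if report is not None:
        report.n_input_genes = X.n_genes
        report.entropy_bits = h
        report.n_after_entropy = len(keep)
    return X.subset_genes(keep)


def soft_connectivity(X: ExpressionMatrix, beta: float) -> pd.Series:
    """Soft network degree k_i = sum_{j != i} |cor(x_i, x_j)|^beta (Pearson)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples")
    vals = X.values.to_numpy()
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = X.gene_ids[sd == 0][0]
        raise ValueError(f"zero-variance gene in connectivity input: {bad!r}")
    r = np.corrcoef(vals)
    np.fill_diagonal(r, 0.0)
    k = (np.abs(r) ** beta).sum(axis=1)
    return pd.Series(k, index=X.gene_ids, name="connectivity")


def connectivity_filter(
    X: ExpressionMatrix,
    k_min: float = DEFAULT_K_MIN,
    beta: float = 6.0,
    report: QcReport | None = None,
) -> ExpressionMatrix:
    """Retain genes with soft connectivity k_i >= k_min (inclusive)."""
    k = soft_connectivity(X, beta)
    keep = k.index[k >= k_min]
    if len(keep) == 0:
        raise ValueError(
            f"connectivity filter at k_min={k_min} removed every gene; "
            "downstream network would be empty"
        )
    if report is not None:
        report.connectivity = k
        report.n_after_connectivity = len(keep)
    return X.subset_genes(keep)


def run_qc(
    X: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold_bits: float = DEFAULT_ENTROPY_BITS,
    n_bins: int = DEFAULT_N_BINS,
    k_min: float = DEFAULT_K_MIN,
    beta: float = 6.0,
) -> tuple[ExpressionMatrix, QcReport]:
    """Full cascade: transform -> entropy filter -> connectivity filter.

    Genes left constant after the transform are removed with the entropy
    filter (they score 0 bits) before connectivity is computed, so the
    connectivity stage never sees a zero-variance gene as long as
    ``threshold_bits`` is positive.
    """
    report = QcReport()
    Xt = log2_transform(X, pseudocount, report=report)
    Xe = entropy_filter(Xt, threshold_bits, n_bins, report=report)
    Xk = connectivity_filter(Xe, k_min, beta, report=report)
    return Xk, report
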