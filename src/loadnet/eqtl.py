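"""Variant QC and covariate-adjusted linear-regression eQTL scanning.

Variant-level QC applies, in order, a minimum call rate (default 0.8),
a minimum minor allele frequency (default 0.02) and a Hardy-Weinberg
exact-test threshold (default 1e-05), reporting per-filter exclusion
counts. The scan then regresses each gene's (log2) expression on each
variant's additive alt-allele dosage plus covariates, complete-case per
variant, and reports beta, SE, t and Student p for the dosage term —
the MatrixEQTL-style additive model. A QQ summary with a genomic
inflation factor supports the usual diagnostic plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "call_rate",
    "maf",
    "hwe_exact_test",
    "variant_qc",
    "fit_eqtl",
    "scan_all_pairs",
    "qq_points",
    "EqtlScan",
    "EqtlResults",
]

DEFAULT_MIN_CALL = 0.8
DEFAULT_MIN_MAF = 0.02
DEFAULT_HWE_ALPHA = 1e-5
DEFAULT_P_REPORT = 1e-5

TABLE_COLUMNS = ["Gene", "rsID", "Beta", "p-Value"]


class SkippedPairError(ValueError):
    """A single gene-variant fit that cannot be performed (e.g. the
    variant is monomorphic among complete cases)."""


def call_rate(g) -> float:
    """Fraction of non-missing calls for one variant."""
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise ValueError("empty dosage vector")
    return float(np.isfinite(g).mean())


def maf(g) -> float:
    """Minor allele frequency from additive dosages (missing ignored)."""
    g = np.asarray(g, dtype=float)
    called = g[np.isfinite(g)]
    if called.size == 0:
        raise ValueError("no called genotypes")
    f = called.sum() / (2 * called.size)
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test, two-sided by probability mass.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote configurations no more probable than the observed
    one (the standard SNP-HWE procedure). Monomorphic sites have a single
    possible configuration and return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise ValueError("genotype counts must be non-negative, not all zero")
    n = n_AA + n_Aa + n_aa
    rare = 2 * min(n_AA, n_aa) + n_Aa
    # possible heterozygote counts share the parity of the rare-allele count
    het_min = rare % 2
    het_max = rare
    probs = {}
    # start from the mode-ish midpoint and fill with the standard recurrence
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != het_min:
        mid += 1
    probs[mid] = 1.0
    # P(h-2)/P(h) = h(h-1) / (4 (hom_rare+1)(hom_common+1))
    h = mid
    while h - 2 >= het_min:
        hom_r_cur = (rare - h) // 2
        hom_c_cur = n - h - hom_r_cur
        probs[h - 2] = probs[h] * h * (h - 1) / (
            4.0 * (hom_r_cur + 1) * (hom_c_cur + 1)
        )
        h -= 2
    h = mid
    while h + 2 <= het_max:
        hom_r_cur = (rare - h) // 2
        hom_c_cur = n - h - hom_r_cur
        probs[h + 2] = probs[h] * 4.0 * hom_r_cur * hom_c_cur / (
            (h + 2) * (h + 1)
        )
        h += 2
    total = sum(probs.values())
    obs = probs[n_Aa] / total
    p = sum(v for v in probs.values() if v / total <= obs * (1 + 1e-12)) / total
    return float(min(1.0, p))


@dataclass
class VariantQcCounts:
    n_input: int = 0
    fail_call_rate: int = 0
    fail_maf: int = 0
    fail_hwe: int = 0

    @property
    def n_pass(self) -> int:
        return self.n_input - self.fail_call_rate - self.fail_maf - self.fail_hwe


def variant_qc(
    G: GenotypeMatrix,
    min_call: float = DEFAULT_MIN_CALL,
    min_maf: float = DEFAULT_MIN_MAF,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
) -> tuple[GenotypeMatrix, VariantQcCounts]:
    """Sequential call-rate -> MAF -> HWE filtering with per-filter counts.

    A variant failing an earlier filter is not tested by later ones, so
    exclusion counts attribute each variant to the first filter it fails.
    """
    counts = VariantQcCounts(n_input=G.n_variants)
    dos = G.dosages.to_numpy()
    keep = []
    for i, vid in enumerate(G.variant_ids):
        g = dos[i]
        if call_rate(g) < min_call:
            counts.fail_call_rate += 1
            continue
        if maf(g) < min_maf:
            counts.fail_maf += 1
            continue
        called = g[np.isfinite(g)]
        n_aa = int((called == 2).sum())
        n_het = int((called == 1).sum())
        n_AA = int((called == 0).sum())
        if hwe_exact_test(n_AA, n_het, n_aa) < hwe_alpha:
            counts.fail_hwe += 1
            continue
        keep.append(vid)
    if not keep:
        warnings.warn("variant QC removed every variant", stacklevel=2)
        return GenotypeMatrix(G.dosages.iloc[0:0], G.meta.iloc[0:0]), counts
    return G.subset_variants(keep), counts


def _ols_dosage_term(Y: np.ndarray, g: np.ndarray, C: np.ndarray | None):
    """OLS of each row of Y on [1, g, C]; stats for the dosage column.

    Y is genes x samples (complete cases only). Returns (beta, se, t, p,
    df) arrays over genes.
    """
    n = g.size
    cols = [np.ones(n), g]
    if C is not None and C.size:
        cols.extend(C.T)
    D = np.column_stack(cols)
    rank = np.linalg.matrix_rank(D)
    if C is not None and C.size and rank < D.shape[1]:
        # distinguish a collinear covariate block from a degenerate genotype
        base = np.column_stack([np.ones(n), *C.T])
        if np.linalg.matrix_rank(base) < base.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
        raise SkippedPairError("genotype collinear with covariates")
    df = n - rank
    if df < 1:
        raise SkippedPairError("no residual degrees of freedom")
    xtx_inv = np.linalg.pinv(D.T @ D)
    B = xtx_inv @ D.T @ Y.T          # coefficients x genes
    resid = Y.T - D @ B
    sigma2 = (resid**2).sum(axis=0) / df
    beta = B[1]
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    return beta, se, t, p, df


def fit_eqtl(y, g, C: pd.DataFrame | np.ndarray | None = None) -> dict:
    """Single gene x variant OLS fit: y ~ intercept + dosage + covariates.

    Samples with a missing dosage are dropped (complete-case). Returns a
    dict with beta, se, t, p, df and n for the dosage term. Raises
    :class:`SkippedPairError` when the variant is monomorphic among
    complete cases.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    Cv = None if C is None else np.asarray(C, dtype=float)
    mask = np.isfinite(g)
    y, g = y[mask], g[mask]
    if Cv is not None:
        Cv = Cv[mask]
    n_cov = 0 if Cv is None else Cv.shape[1]
    if y.size < n_cov + 3:
        raise SkippedPairError(
            f"only {y.size} complete cases for {n_cov} covariates"
        )
    if np.ptp(g) == 0:
        raise SkippedPairError("zero genotype variance after missing-drop")
    beta, se, t, p, df = _ols_dosage_term(y[None, :], g, Cv)
    return {
        "beta": float(beta[0]),
        "se": float(se[0]),
        "t": float(t[0]),
        "p": float(p[0]),
        "df": int(df),
        "n": int(y.size),
    }


def scan_all_pairs(
    X: ExpressionMatrix,
    G: GenotypeMatrix,
    C: pd.DataFrame | None = None,
    p_report: float = DEFAULT_P_REPORT,
    m: int | None = None,
    paper_mode: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """All gene x variant regressions; keep records with p <= p_report.

    Covariates (samples x covariates) are shared across fits; samples
    with missing dosage are dropped per variant. Bonferroni correction
    uses m = number of tests by default, or subjects x variants when
    ``paper_mode`` is set.
    """
    if list(X.sample_ids) != list(G.sample_ids):
        raise ValueError("expression and genotype sample ids differ")
    if C is not None and list(C.index) != list(X.sample_ids):
        raise ValueError("covariate sample ids differ from expression")
    Y_full = X.values.to_numpy(dtype=float)
    Cv = None if C is None else C.to_numpy(dtype=float)
    dos = G.dosages.to_numpy(dtype=float)
    rows, n_tests, n_skipped = [], 0, 0
    for i, vid in enumerate(G.variant_ids):
        g = dos[i]
        mask = np.isfinite(g)
        gs = g[mask]
        n_cov = 0 if Cv is None else Cv.shape[1]
        if gs.size < n_cov + 3 or np.ptp(gs) == 0:
            n_skipped += X.n_genes
            continue
        try:
            beta, se, t, p, df = _ols_dosage_term(
                Y_full[:, mask], gs, None if Cv is None else Cv[mask]
            )
        except SkippedPairError:
            n_skipped += X.n_genes
            continue
        n_tests += X.n_genes
        hit = p <= p_report
        if hit.any():
            idx = np.flatnonzero(hit)
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": X.gene_ids[idx],
                        "variant_id": vid,
                        "beta": beta[idx],
                        "se": se[idx],
                        "t": t[idx],
                        "p": p[idx],
                        "n": int(gs.size),
                    }
                )
            )
    records = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["gene_id", "variant_id", "beta", "se", "t", "p", "n"]
        )
    )
    if paper_mode:
        m_tests = X.n_samples * G.n_variants
    else:
        m_tests = m if m is not None else max(n_tests, 1)
    if len(records):
        records["p_bonferroni"] = np.minimum(1.0, records["p"] * m_tests)
        records = records.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        records["p_bonferroni"] = pd.Series(dtype=float)
    info = {"n_tests": n_tests, "n_skipped": n_skipped, "m": m_tests}
    return records, info


def qq_points(p) -> tuple[pd.DataFrame, float]:
    """Expected vs observed -log10 p quantiles plus genomic inflation.

    Returns (DataFrame with ``expected``/``observed`` columns sorted from
    the strongest signal down, lambda_GC = median observed chi-square /
    its null median). Zero p-values are floored at the smallest positive
    double.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    p = np.maximum(p, np.nextafter(0.0, 1.0))
    n = p.size
    srt = np.sort(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(srt)
    lam = float(
        np.median(stats.chi2.isf(srt, df=1)) / stats.chi2.ppf(0.5, df=1)
    )
    return pd.DataFrame({"expected": expected, "observed": observed}), lam


@dataclass
class EqtlResults:
    """QC'd, scanned eQTL output."""

    records: pd.DataFrame
    qc_counts: VariantQcCounts
    scan_info: dict
    genotypes: GenotypeMatrix = None

    def table(self) -> pd.DataFrame:
        """Conventional per-association report (Gene, rsID, Beta, p-Value)."""
        df = self.records.rename(
            columns={
                "gene_id": "Gene",
                "variant_id": "rsID",
                "beta": "Beta",
                "p_bonferroni": "p-Value",
            }
        )
        return df[TABLE_COLUMNS + ["se", "t", "p"]]

    def qq(self) -> tuple[pd.DataFrame, float]:
        return qq_points(self.records["p"])

    def summary(self) -> str:
        c = self.qc_counts
        return (
            f"eQTL scan: {c.n_input} variants in "
            f"(-{c.fail_call_rate} call-rate, -{c.fail_maf} MAF, "
            f"-{c.fail_hwe} HWE) -> {c.n_pass} tested; "
            f"{self.scan_info['n_tests']} regressions, "
            f"{len(self.records)} below the reporting threshold "
            f"(Bonferroni m={self.scan_info['m']})"
        )

    def to_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t", index=False)


class EqtlScan:
    """Additive-model eQTL scan with variant QC.

    Parameters
    ----------
    expression
        Log2-transformed expression matrix (genes x samples).
    genotypes
        Dosage matrix; sample ids must match the expression matrix.
    covariates
        Optional samples x covariates DataFrame included in every
        regression (e.g. the clinical covariates, or technical ones).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        genotypes: GenotypeMatrix,
        covariates: pd.DataFrame | None = None,
    ):
        self.expression = expression
        self.genotypes = genotypes
        self.covariates = covariates

    def fit(
        self,
        min_call: float = DEFAULT_MIN_CALL,
        min_maf: float = DEFAULT_MIN_MAF,
        hwe_alpha: float = DEFAULT_HWE_ALPHA,
        p_report: float = DEFAULT_P_REPORT,
        m: int | None = None,
        paper_mode: bool = False,
    ) -> EqtlResults:
        qcd, counts = variant_qc(self.genotypes, min_call, min_maf, hwe_alpha)
        records, info = scan_all_pairs(
            self.expression,
            qcd,
            self.covariates,
            p_report=p_report,
            m=m,
            paper_mode=paper_mode,
        )
        return EqtlResults(
            records=records, qc_counts=counts, scan_info=info, genotypes=qcd
        )
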