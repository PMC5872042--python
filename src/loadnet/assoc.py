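"""Clinical-trait concordance and weighted gene-trait association testing.

The screen mirrors a standard neuropathology workflow: check the
concordance of the clinical covariates (pairwise Pearson correlation,
PCA of the trait correlation matrix), then test every gene or module
eigengene against the clinical traits. Each association carries both a
standard p-value (Student t on the Pearson correlation) and a *weighted*
p-value: the Fisher z-statistic is scaled by a weight derived from the
trait's coefficient on the 2nd clinical principal component (default
scale 0.5), and converted to a two-sided normal tail probability.
Associations more than 3 SD from the mean z are trimmed, then Bonferroni
and Benjamini-Hochberg corrections are applied; an external test count m
(e.g. subjects x transcripts) is supported for both.

Functional annotation is a flat gene -> term map; keyword filtering is
case-insensitive substring matching, and term over-representation uses
the hypergeometric upper tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, TraitTable

__all__ = [
    "trait_correlation_matrix",
    "trait_pca",
    "TraitPca",
    "pc_weight",
    "associate",
    "outlier_trim",
    "adjust_pvalues",
    "read_annotation",
    "annotate_and_filter",
    "term_overrepresentation",
    "TraitAssociation",
    "AssociationResults",
]

DEFAULT_PC_SCALE = 0.5      # weight = scale * |trait loading on PC2|
DEFAULT_TRIM_SD = 3.0
DEFAULT_ALPHA_CORRECT = 0.01
DEFAULT_ALPHA_REPORT = 0.05

TABLE_COLUMNS = ["GENE", "P.WEIGHTED", "FDR", "COR.WEIGHTED", "#OF TRAITS"]


def trait_correlation_matrix(T: TraitTable) -> pd.DataFrame:
    """Pairwise Pearson correlation of the traits, complete-case per pair.

    Constant traits produce NaN entries and a warning rather than a
    silent zero.
    """
    df = T.traits
    constant = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(
            f"constant trait(s) {constant}: correlation undefined (NaN)",
            stacklevel=2,
        )
    r = df.corr(method="pearson", min_periods=3)
    np.fill_diagonal(r.values, 1.0)
    for c in constant:
        r.loc[c, :] = np.nan
        r.loc[:, c] = np.nan
        r.loc[c, c] = np.nan
    return r


@dataclass
class TraitPca:
    """PCA of the standardized clinical traits.

    ``loadings`` is traits x PCs with orthonormal columns;
    ``scores`` is samples x PCs (scores @ loadings.T reconstructs the
    standardized data); ``explained_variance`` holds the eigenvalues of
    the trait correlation matrix, summing to the number of traits.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance: pd.Series

    @property
    def explained_fraction(self) -> pd.Series:
        return self.explained_variance / self.explained_variance.sum()


def trait_pca(T: TraitTable, traits: list[str] | None = None) -> TraitPca:
    """Eigendecomposition of the trait correlation matrix.

    Traits are standardized (zero mean, unit variance) internally. Having
    more traits than samples is allowed but flagged with a warning.
    """
    df = T.traits[traits] if traits is not None else T.traits
    if df.shape[1] > df.shape[0]:
        warnings.warn(
            f"{df.shape[1]} traits exceed {df.shape[0]} samples; "
            "trailing components are degenerate",
            stacklevel=2,
        )
    z = (df - df.mean()) / df.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # deterministic sign: largest-|loading| entry of each PC is positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    pcs = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=df.columns, columns=pcs)
    scores = pd.DataFrame(z.to_numpy() @ eigvec, index=df.index, columns=pcs)
    return TraitPca(
        loadings=loadings,
        scores=scores,
        explained_variance=pd.Series(eigval, index=pcs, name="explained_variance"),
    )


def pc_weight(pca: TraitPca, trait: str, scale: float = DEFAULT_PC_SCALE) -> float:
    """Association weight for a trait: scale x |loading of trait on PC2|."""
    if "PC2" not in pca.loadings.columns:
        raise ValueError("PCA has no 2nd principal component")
    if trait not in pca.loadings.index:
        raise KeyError(f"unknown trait {trait!r}")
    return float(scale * abs(pca.loadings.loc[trait, "PC2"]))


def associate(
    X_or_ME: ExpressionMatrix | pd.DataFrame,
    scores: pd.Series,
    weight: float,
    score_id: str = "score",
) -> pd.DataFrame:
    """Correlation screen of every gene/eigengene against one score vector.

    Per row x_i: r = cor(x_i, scores); t = r sqrt(n-2)/sqrt(1-r^2) with a
    two-sided Student p; z = sqrt(n-3) atanh(r) (Fisher transform);
    cor_weighted = weight * r; z_weighted = weight * z;
    p_weighted = two-sided normal tail of z_weighted. Perfect
    correlations get the smallest representable positive p and are
    flagged.
    """
    vals = X_or_ME.values if isinstance(X_or_ME, ExpressionMatrix) else X_or_ME
    vals = vals.loc[:, scores.index] if not vals.columns.equals(scores.index) else vals
    n = vals.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    X = vals.to_numpy(dtype=float)
    y = scores.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    if (denom == 0).any():
        bad = vals.index[denom == 0][0]
        raise ValueError(f"zero-variance row {bad!r} in association input")
    r = np.clip(Xc @ yc / denom, -1.0, 1.0)
    perfect = np.isclose(np.abs(r), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
        z = np.sqrt(n - 3) * np.arctanh(np.where(perfect, np.nan, r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    tiny = np.nextafter(0.0, 1.0)
    p = np.where(perfect, tiny, p)
    z = np.where(perfect, np.sign(r) * np.inf, z)
    zw = weight * z
    with np.errstate(invalid="ignore"):
        pw = 2.0 * stats.norm.sf(np.abs(zw))
    pw = np.where(perfect & (weight > 0), tiny, pw)
    pw = np.where(perfect & (weight == 0), 1.0, pw)
    return pd.DataFrame(
        {
            "gene_id": vals.index,
            "score_id": score_id,
            "n": n,
            "cor": r,
            "t": t,
            "p": p,
            "z": z,
            "cor_weighted": weight * r,
            "z_weighted": zw,
            "p_weighted": pw,
            "weight": weight,
            "flag_perfect": perfect,
        }
    ).reset_index(drop=True)


def outlier_trim(
    records: pd.DataFrame, n_sd: float = DEFAULT_TRIM_SD, column: str = "z"
) -> tuple[pd.DataFrame, int]:
    """Drop associations whose z lies outside mean +/- n_sd * SD.

    Returns (trimmed records, number dropped). Infinite z values (perfect
    correlations) always count as outliers.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to trim")
    z = records[column].to_numpy(dtype=float)
    finite = np.isfinite(z)
    mu, sd = z[finite].mean(), z[finite].std(ddof=1)
    keep = finite & (np.abs(z - mu) <= n_sd * sd)
    return records[keep].reset_index(drop=True), int((~keep).sum())


def adjust_pvalues(p, method: str, m: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment with an optional external test count.

    ``bonferroni``: min(1, p*m). ``bh``: Benjamini-Hochberg step-up using
    m in place of len(p) (the two coincide when m is None). m may exceed
    len(p), supporting corrections quoted against an external number of
    observations.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, len(p) + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(q)
        out[order] = np.minimum(1.0, q)
        return out
    raise ValueError(f"unknown method {method!r}")


def read_annotation(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id <TAB> term) -> gene to term-set map."""
    ann: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term"])
    for gene, term in zip(df["gene_id"], df["term"]):
        ann.setdefault(str(gene), set()).add(str(term))
    return ann


def annotate_and_filter(
    records: pd.DataFrame,
    ann: dict[str, set[str]],
    keywords: list[str],
    alpha: float = DEFAULT_ALPHA_REPORT,
    p_column: str = "p_weighted",
) -> pd.DataFrame:
    """Keyword-filter annotated associations; count significant traits.

    Retains records whose gene carries any functional term containing any
    keyword (case-insensitive substring). Adds a ``terms`` column and
    ``n_traits_significant``: per gene, the number of tested score ids
    with ``p_column`` <= alpha (computed over the *input* records, before
    keyword filtering).
    """
    if not ann:
        warnings.warn("empty annotation map: nothing can match", stacklevel=2)
        return records.iloc[0:0].assign(terms=None, n_traits_significant=0)
    kw = [k.lower() for k in keywords]
    sig = (
        records[records[p_column] <= alpha]
        .groupby("gene_id")["score_id"]
        .nunique()
    )
    out = records.copy()
    out["terms"] = [
        "; ".join(sorted(ann.get(g, set()))) for g in out["gene_id"]
    ]
    out["n_traits_significant"] = (
        out["gene_id"].map(sig).fillna(0).astype(int)
    )
    def hit(gene: str) -> bool:
        return any(
            k in term.lower() for term in ann.get(gene, set()) for k in kw
        )
    mask = out["gene_id"].map(hit)
    return out[mask].reset_index(drop=True)


def term_overrepresentation(hits: set, background: set, term_genes: set) -> float:
    """Hypergeometric upper-tail p for term enrichment among hit genes."""
    hits, background, term_genes = set(hits), set(background), set(term_genes)
    if not hits <= background:
        raise ValueError("hits must be a subset of background")
    extra = term_genes - background
    if extra:
        warnings.warn(
            f"{len(extra)} term genes outside background trimmed", stacklevel=2
        )
        term_genes &= background
    k = len(hits & term_genes)
    return float(
        stats.hypergeom.sf(k - 1, len(background), len(term_genes), len(hits))
    )


@dataclass
class AssociationResults:
    """Weighted association screen output.

    ``records`` is the long table (one row per gene x trait) after
    outlier trimming and multiple-testing correction. ``table()``
    collapses it to the per-gene report with the conventional column set
    (GENE, P.WEIGHTED, FDR, COR.WEIGHTED, #OF TRAITS).
    """

    records: pd.DataFrame
    pca: TraitPca
    trait_correlations: pd.DataFrame
    n_trimmed: int
    m_tests: int
    alpha: float
    weights: dict[str, float] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Per-gene summary: lowest corrected weighted p and its correlation."""
        rows = []
        for gene, grp in self.records.groupby("gene_id", sort=True):
            i = grp["p_weighted_bonferroni"].idxmin()
            rows.append(
                {
                    "GENE": gene,
                    "P.WEIGHTED": grp.loc[i, "p_weighted_bonferroni"],
                    "FDR": grp["fdr"].min(),
                    "COR.WEIGHTED": grp.loc[i, "cor_weighted"],
                    "#OF TRAITS": int(grp["n_traits_significant"].max())
                    if "n_traits_significant" in grp
                    else int((grp["p_weighted"] <= self.alpha).sum()),
                }
            )
        return (
            pd.DataFrame(rows, columns=TABLE_COLUMNS)
            .sort_values("P.WEIGHTED", kind="stable")
            .reset_index(drop=True)
        )

    def summary(self) -> str:
        n_sig = int((self.records["p_weighted_bonferroni"] <= self.alpha).sum())
        return (
            f"Association screen: {self.records['gene_id'].nunique()} genes x "
            f"{self.records['score_id'].nunique()} traits "
            f"({len(self.records)} tests, m={self.m_tests}); "
            f"{self.n_trimmed} outlier associations trimmed; "
            f"{n_sig} corrected weighted p <= {self.alpha}"
        )

    def to_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t", index=False)


class TraitAssociation:
    """Weighted gene/eigengene-trait association model.

    Parameters
    ----------
    data
        Expression matrix (genes x samples) or eigengene DataFrame
        (modules x samples).
    trait_table
        Clinical traits; sample ids must match ``data``.
    annotation
        Optional gene -> functional-term map for keyword filtering.

    The fit screens every row of ``data`` against each clinical trait,
    weighting each trait's associations by ``scale x |loading on PC2|``
    of the clinical PCA — traits aligned with the dominant
    neuropathology axis count more.
    """

    def __init__(
        self,
        data: ExpressionMatrix | pd.DataFrame,
        trait_table: TraitTable,
        annotation: dict[str, set[str]] | None = None,
    ):
        self.data = data
        self.traits = trait_table
        self.annotation = annotation

    def fit(
        self,
        traits: list[str] | None = None,
        scale: float = DEFAULT_PC_SCALE,
        trim_sd: float = DEFAULT_TRIM_SD,
        alpha: float = DEFAULT_ALPHA_CORRECT,
        alpha_report: float = DEFAULT_ALPHA_REPORT,
        m: int | None = None,
        paper_mode_m: bool = False,
        keywords: list[str] | None = None,
    ) -> AssociationResults:
        trait_names = traits or self.traits.trait_names
        pca = trait_pca(self.traits, traits)
        corr = trait_correlation_matrix(self.traits)
        vals = (
            self.data.values
            if isinstance(self.data, ExpressionMatrix)
            else self.data
        )
        parts, weights = [], {}
        for trait in trait_names:
            w = pc_weight(pca, trait, scale)
            weights[trait] = w
            parts.append(
                associate(vals, self.traits.values[trait], w, score_id=trait)
            )
        records = pd.concat(parts, ignore_index=True)
        records, n_trimmed = outlier_trim(records, n_sd=trim_sd)
        if paper_mode_m:
            # correction quoted against subjects x transcripts
            m_tests = vals.shape[1] * vals.shape[0]
        else:
            m_tests = m if m is not None else len(records)
        records["p_weighted_bonferroni"] = adjust_pvalues(
            records["p_weighted"], "bonferroni", m_tests
        )
        records["fdr"] = adjust_pvalues(records["p_weighted"], "bh", m_tests)
        sig = (
            records[records["p_weighted"] <= alpha_report]
            .groupby("gene_id")["score_id"]
            .nunique()
        )
        records["n_traits_significant"] = (
            records["gene_id"].map(sig).fillna(0).astype(int)
        )
        if keywords:
            if self.annotation is None:
                raise ValueError("keyword filtering requires an annotation map")
            records = annotate_and_filter(
                records,
                self.annotation,
                keywords,
                alpha=alpha_report,
                p_column="p_weighted",
            )
        return AssociationResults(
            records=records,
            pca=pca,
            trait_correlations=corr,
            n_trimmed=n_trimmed,
            m_tests=m_tests,
            alpha=alpha,
            weights=weights,
        )
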