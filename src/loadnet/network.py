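"""Weighted co-expression network construction and module detection.

Implements the WGCNA-style pipeline: soft-thresholded adjacency
a_ij = |cor(x_i, x_j)|^beta (unsigned network), topological overlap
matrix (TOM), average-linkage hierarchical module detection on 1 - TOM,
and module eigengenes (first principal component of each module's
standardized expression).

The :class:`CoexpressionNetwork` model wraps the functional core: build
it from a QC'd :class:`~loadnet.containers.ExpressionMatrix`, call
``fit()``, and read modules/eigengenes off the returned
:class:`NetworkResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

__all__ = [
    "adjacency",
    "pick_soft_threshold",
    "scale_free_fit",
    "tom",
    "cluster_modules",
    "module_eigengenes",
    "CoexpressionNetwork",
    "NetworkResults",
]

DEFAULT_CANDIDATE_BETAS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
DEFAULT_CUT_HEIGHT = 0.99
DEFAULT_MIN_MODULE_SIZE = 30


def _corr_abs(X: ExpressionMatrix) -> np.ndarray:
    vals = X.values.to_numpy()
    if (vals.std(axis=1) == 0).any():
        bad = X.gene_ids[vals.std(axis=1) == 0][0]
        raise ValueError(f"zero-variance gene: {bad!r}")
    r = np.abs(np.corrcoef(vals))
    np.clip(r, 0.0, 1.0, out=r)
    return r


def adjacency(X: ExpressionMatrix, beta: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor|^beta, zero diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = _corr_abs(X) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=X.gene_ids, columns=X.gene_ids)


def scale_free_fit(k, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a degree sequence.

    Bins connectivities into equal-width bins, regresses log10(bin
    frequency) on log10(bin mean connectivity), and returns (R^2, slope).
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        raise ValueError("degenerate degree sequence: all connectivities equal")
    counts, edges = np.histogram(k, bins=n_bins)
    sums, _ = np.histogram(k, bins=edges, weights=k)
    mask = counts > 0
    x = np.log10(sums[mask] / counts[mask])
    y = np.log10(counts[mask] / k.size)
    if mask.sum() < 3:
        raise ValueError("too few occupied bins for a scale-free fit")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - (resid**2).sum() / ss_tot
    return float(r2), float(slope)


def pick_soft_threshold(
    X: ExpressionMatrix,
    candidate_betas=DEFAULT_CANDIDATE_BETAS,
    r2_target: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Smallest beta whose degree distribution fits scale-free topology.

    Returns (beta, diagnostics) where diagnostics has one row per
    candidate (beta, r2, slope, mean_k). Falls back to the best-fitting
    beta, with a warning, when no candidate reaches ``r2_target``.
    """
    betas = sorted(candidate_betas)
    rows = []
    r = _corr_abs(X)
    np.fill_diagonal(r, 0.0)
    for b in betas:
        k = (r**b).sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"beta": b, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
    diag = pd.DataFrame(rows).set_index("beta")
    passing = diag.index[diag["r2"] >= r2_target]
    if len(passing):
        return float(passing[0]), diag
    best = float(diag["r2"].idxmax())
    warnings.warn(
        f"no candidate beta reached scale-free R^2 >= {r2_target}; "
        f"using beta={best} (R^2={diag.loc[best, 'r2']:.3f})",
        stacklevel=2,
    )
    return best, diag


def tom(A: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix.

    tom_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with k_i = sum_u a_iu; diagonal defined as 1. The denominator
    vanishes only when min(k) = 0 and a_ij = 1, where the overlap is
    defined as 1.
    """
    a = A.to_numpy()
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of a is 0, so u=i,j terms drop out
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 1.0)
    np.fill_diagonal(t, 1.0)
    np.clip(t, 0.0, 1.0, out=t)
    return pd.DataFrame(t, index=A.index, columns=A.columns)


def cluster_modules(
    T: pd.DataFrame,
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM, cut at ``cut_height``.

    Clusters smaller than ``min_size`` are relabeled 0 (unassigned /
    "grey"). Surviving modules are labeled 1..K by decreasing size, ties
    broken by the earliest member gene for determinism.
    """
    n = T.shape[0]
    if min_size > n:
        raise ValueError(f"min_size={min_size} exceeds gene count {n}")
    d = 1.0 - T.to_numpy()
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    clusters = pd.Series(raw).groupby(raw).groups
    keep = [
        (len(ix), min(ix), cid)
        for cid, ix in clusters.items()
        if len(ix) >= min_size
    ]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, _, cid) in enumerate(keep, start=1):
        labels[raw == cid] = new_label
    return pd.Series(labels, index=T.index, name="module")


def module_eigengenes(
    X: ExpressionMatrix, modules: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardized expression.

    Member genes are standardized (zero mean, unit variance, ddof=1)
    across samples; the eigengene is the first PC of the samples-by-genes
    submatrix, rescaled to unit variance, with sign fixed so it
    correlates non-negatively with the mean member profile. Returns
    (eigengenes modules x samples, variance-explained per module).
    """
    rows, varexp, names = [], [], []
    for label in sorted(set(modules) - {0}):
        genes = modules.index[modules == label]
        if len(genes) < 2:
            raise ValueError(f"module {label} has fewer than 2 genes")
        sub = X.values.loc[genes].to_numpy().T  # samples x genes
        sd = sub.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = genes[sd == 0][0]
            raise ValueError(f"zero-variance gene {bad!r} in module {label}")
        z = (sub - sub.mean(axis=0)) / sd
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        eig = pc1 / pc1.std(ddof=1)
        mean_profile = z.mean(axis=1)
        if np.dot(eig - eig.mean(), mean_profile) < 0:
            eig = -eig
        rows.append(eig)
        varexp.append(float(s[0] ** 2 / (s**2).sum()))
        names.append(label)
    eigengenes = pd.DataFrame(
        rows, index=pd.Index(names, name="module"), columns=X.sample_ids
    )
    return eigengenes, pd.Series(varexp, index=eigengenes.index, name="variance_explained")


@dataclass
class NetworkResults:
    """Fitted co-expression network: modules, eigengenes, diagnostics."""

    beta: float
    scale_free_r2: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series
    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    threshold_diagnostics: pd.DataFrame | None = None

    @property
    def n_modules(self) -> int:
        return int((self.eigengenes.shape[0]))

    def module_sizes(self) -> pd.Series:
        return self.modules[self.modules > 0].value_counts().sort_index()

    def summary(self) -> str:
        sizes = ", ".join(
            f"{m}:{s}" for m, s in self.module_sizes().items()
        )
        lines = [
            "Co-expression network",
            f"  genes: {len(self.modules)}  soft power beta: {self.beta:g} "
            f"(scale-free R^2 = {self.scale_free_r2:.3f})",
            f"  modules (label:size): {sizes or 'none'}  "
            f"unassigned: {int((self.modules == 0).sum())}",
            "  variance explained by eigengene: "
            + ", ".join(
                f"{m}:{v:.2f}" for m, v in self.variance_explained.items()
            ),
        ]
        return "\n".join(lines)


class CoexpressionNetwork:
    """Weighted co-expression network model for a QC'd expression matrix.

    Parameters
    ----------
    X
        Log2-transformed, QC'd expression matrix (no zero-variance genes).

    Examples
    --------
    >>> net = CoexpressionNetwork(expr_qc).fit(min_module_size=30)
    >>> net.modules.value_counts()
    """

    def __init__(self, X: ExpressionMatrix):
        self.X = X

    def fit(
        self,
        beta: float | None = None,
        candidate_betas=DEFAULT_CANDIDATE_BETAS,
        r2_target: float = 0.8,
        min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
        cut_height: float = DEFAULT_CUT_HEIGHT,
    ) -> NetworkResults:
        diag = None
        if beta is None:
            beta, diag = pick_soft_threshold(self.X, candidate_betas, r2_target)
        A = adjacency(self.X, beta)
        if diag is not None and beta in diag.index:
            r2 = float(diag.loc[beta, "r2"])
        else:
            r2, _ = scale_free_fit(A.to_numpy().sum(axis=1))
        T = tom(A)
        modules = cluster_modules(T, min_size=min_module_size, cut_height=cut_height)
        if (modules > 0).any():
            eigengenes, varexp = module_eigengenes(self.X, modules)
        else:
            eigengenes = pd.DataFrame(columns=self.X.sample_ids)
            varexp = pd.Series(dtype=float)
        return NetworkResults(
            beta=float(beta),
            scale_free_r2=r2,
            adjacency=A,
            tom=T,
            modules=modules,
            eigengenes=eigengenes,
            variance_explained=varexp,
            threshold_diagnostics=diag,
        )
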