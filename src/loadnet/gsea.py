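"""Gene set enrichment analysis with phenotype permutation.

Implements the classic two-class GSEA procedure from scratch: genes are
ranked by the log2 ratio of class means, a weighted Kolmogorov-Smirnov
style running sum yields an enrichment score (ES) per gene set, class
labels are permuted to build a null ES distribution, the normalized
enrichment score (NES) divides the ES by the mean same-sign permuted ES,
and set-level FDR q-values compare the observed NES distribution with
the pooled permuted one.

Sets come from GMT files; sizes outside [min_size, max_size] (after
restriction to analyzed genes) are dropped with a report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "rank_metric_log2_ratio",
    "enrichment_score",
    "permutation_null",
    "normalize_es",
    "gsea_fdr",
    "read_gmt",
    "write_gmt",
    "GeneSetCollection",
    "Gsea",
    "GseaResults",
    "EnrichmentResult",
]

DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500
DEFAULT_EXPONENT = 1.0


def rank_metric_log2_ratio(
    X: ExpressionMatrix, classes: pd.Series, floor: float | None = None
) -> pd.Series:
    """Per-gene log2 ratio of class means, sorted descending.

    ``classes`` maps sample id -> "case"/"control"; both classes need at
    least 2 samples. Class means are floored at ``floor`` (default: 1% of
    the smallest positive value in the matrix) so the ratio stays
    defined for zero means. Ties are broken lexicographically by gene id
    so the ranking is strict and deterministic.
    """
    classes = classes.loc[X.sample_ids]
    case = X.values.loc[:, classes == "case"]
    ctrl = X.values.loc[:, classes == "control"]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    if floor is None:
        pos = X.values.to_numpy()
        pos = pos[pos > 0]
        if pos.size == 0:
            raise ValueError("matrix has no positive values")
        floor = float(pos.min()) * 0.01
    mc = np.maximum(case.mean(axis=1).to_numpy(), floor)
    mm = np.maximum(ctrl.mean(axis=1).to_numpy(), floor)
    metric = np.log2(mc / mm)
    s = pd.Series(metric, index=X.gene_ids, name="metric")
    order = np.lexsort((s.index.to_numpy(), -s.to_numpy()))
    return s.iloc[order]


def enrichment_score(
    ranked: pd.Series, gene_set, exponent: float = DEFAULT_EXPONENT
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted running-sum enrichment score for one gene set.

    Walking down the ranked list, hits increment the running sum by
    |metric|^exponent (normalized over the set's hits) and misses
    decrement by 1/(N - |S|). The ES is the deviation of maximum
    magnitude. Returns (ES, running sum per rank, hit indices).
    """
    genes = ranked.index
    hit = genes.isin(set(gene_set)).astype(float)
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if nh == len(genes):
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.to_numpy()) ** exponent
    sw = (w * hit).sum()
    if sw == 0:
        warnings.warn(
            "all hit metrics are zero; falling back to unweighted ES",
            stacklevel=2,
        )
        w = np.ones_like(w)
        sw = float(nh)
    steps = np.where(hit > 0, w / sw, -1.0 / (len(genes) - nh))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running, np.flatnonzero(hit > 0)


def _permuted_metrics(
    X: ExpressionMatrix,
    classes: pd.Series,
    n_perm: int,
    rng: np.random.Generator,
    floor: float | None = None,
) -> np.ndarray:
    """Metric matrix (n_perm x genes) under shuffled class labels."""
    classes = classes.loc[X.sample_ids]
    labels = (classes == "case").to_numpy()
    n_case = int(labels.sum())
    n = labels.size
    if comb(n, n_case) < n_perm:
        warnings.warn(
            f"only {comb(n, n_case)} distinct label permutations exist; "
            f"sampling {n_perm} with replacement",
            stacklevel=2,
        )
    V = X.values.to_numpy()
    if floor is None:
        pos = V[V > 0]
        floor = float(pos.min()) * 0.01
    ind = np.empty((n, n_perm))
    for j in range(n_perm):
        ind[:, j] = rng.permutation(labels)
    mc = np.maximum(V @ ind / n_case, floor)
    mm = np.maximum(V @ (1 - ind) / (n - n_case), floor)
    return np.log2(mc / mm).T  # n_perm x genes (in X.gene_ids order)


def permutation_null(
    X: ExpressionMatrix,
    classes: pd.Series,
    gene_set,
    n_perm: int,
    seed: int = 0,
    exponent: float = DEFAULT_EXPONENT,
    floor: float | None = None,
) -> np.ndarray:
    """Null ES sample for one set under phenotype permutation."""
    rng = np.random.default_rng(seed)
    metrics = _permuted_metrics(X, classes, n_perm, rng, floor)
    gene_rank = np.argsort(np.argsort(X.gene_ids.to_numpy()))
    out = np.empty(n_perm)
    genes = X.gene_ids
    for j in range(n_perm):
        order = np.lexsort((gene_rank, -metrics[j]))
        ranked = pd.Series(metrics[j][order], index=genes[order])
        out[j], _, _ = enrichment_score(ranked, gene_set, exponent)
    return out


def normalize_es(
    es: float, null: np.ndarray, mode: str = "sign_matched"
) -> tuple[float, float]:
    """NES and nominal p from an ES and its permutation null.

    ``sign_matched`` (standard practice): NES = ES / mean |same-sign
    null ES|; the nominal p is the add-one-corrected fraction of
    same-sign null values at least as extreme. ``all`` divides by the
    mean |null ES| over every permutation instead.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    if mode == "all":
        ref = null
    elif mode == "sign_matched":
        ref = null[np.sign(null) == np.sign(es)] if es != 0 else null
    else:
        raise ValueError(f"unknown NES mode {mode!r}")
    if ref.size == 0:
        warnings.warn(
            "no same-sign permutation scores: NES undefined", stacklevel=2
        )
        return float("nan"), 1.0
    nes = es / np.abs(ref).mean()
    p = (1.0 + (np.abs(ref) >= abs(es)).sum()) / (1.0 + ref.size)
    return float(nes), float(min(1.0, p))


def gsea_fdr(observed: pd.Series, permuted: dict[str, np.ndarray]) -> pd.Series:
    """FDR q per set from observed and pooled permuted NES distributions.

    q = [fraction of same-sign pooled permuted NES at least as extreme]
      / [fraction of same-sign observed NES at least as extreme],
    capped at 1, with monotonicity enforced from the most extreme NES
    down within each sign.
    """
    if len(observed) < 2:
        warnings.warn(
            "a single gene set gives no meaningful FDR; q set to NaN",
            stacklevel=2,
        )
    pool = np.concatenate([np.asarray(v, float) for v in permuted.values()])
    obs = observed.to_numpy(dtype=float)
    q = pd.Series(np.nan, index=observed.index, name="fdr_q")
    for name, nes in observed.items():
        if not np.isfinite(nes):
            continue
        same_pool = pool[np.sign(pool) == np.sign(nes)] if nes != 0 else pool
        same_obs = obs[np.sign(obs) == np.sign(nes)] if nes != 0 else obs
        num = (
            (np.abs(same_pool) >= abs(nes)).mean() if same_pool.size else 0.0
        )
        den = (np.abs(same_obs) >= abs(nes)).mean()
        q[name] = min(1.0, num / den) if den > 0 else 1.0
    # monotone: a more extreme NES never has a larger q. Walk from the
    # least extreme set up, carrying the running minimum (q-value style).
    for sign in (1, -1):
        names = [n for n in observed.index if np.sign(observed[n]) == sign]
        names.sort(key=lambda n: abs(observed[n]))
        running = np.inf
        for n in names:
            if np.isfinite(q[n]):
                running = min(running, q[n])
                q[n] = running
    return q


@dataclass
class GeneSetCollection:
    """Named gene sets plus a record of sets dropped by size filtering."""

    sets: dict[str, list[str]]
    source: str = ""
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(
    path,
    restrict_to=None,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> GeneSetCollection:
    """Parse a GMT file (name <TAB> description <TAB> members...).

    Membership is intersected with ``restrict_to`` (the analyzed genes)
    when given; sets whose filtered size falls outside
    [min_size, max_size] are dropped and recorded in ``dropped``.
    """
    lines = [
        ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if not lines:
        raise ValueError(f"empty GMT file: {path}")
    universe = None if restrict_to is None else set(restrict_to)
    sets: dict[str, list[str]] = {}
    dropped: dict[str, int] = {}
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {ln[:60]!r}")
        name, _desc, members = parts[0], parts[1], parts[2:]
        if name in sets or name in dropped:
            raise ValueError(f"duplicate gene set name {name!r}")
        if universe is not None:
            members = [g for g in members if g in universe]
        if not (min_size <= len(members) <= max_size):
            dropped[name] = len(members)
            continue
        sets[name] = members
    return GeneSetCollection(sets=sets, source=str(path), dropped=dropped)


def write_gmt(collection: GeneSetCollection | dict, path) -> None:
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write(name + "\tloadnet\t" + "\t".join(members) + "\n")


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    running_sum: np.ndarray
    hit_indices: np.ndarray
    null_es: np.ndarray


@dataclass
class GseaResults:
    """Per-set enrichment statistics plus running-sum profiles."""

    results: dict[str, EnrichmentResult]
    ranked: pd.Series
    n_perm: int

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "set": r.name,
                "size": r.size,
                "ES": r.es,
                "NES": r.nes,
                "nominal_p": r.nominal_p,
                "fdr_q": r.fdr_q,
            }
            for r in self.results.values()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values("nominal_p", kind="stable")
            .reset_index(drop=True)
        )

    def summary(self) -> str:
        t = self.table()
        top = t.iloc[0]
        return (
            f"GSEA: {len(t)} sets x {self.n_perm} phenotype permutations; "
            f"top set {top['set']!r} ES={top['ES']:.3f} NES={top['NES']:.3f} "
            f"p={top['nominal_p']:.3g} q={top['fdr_q']:.3g}"
        )

    def to_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t", index=False)

    def running_sum_tsv(self, name: str, path) -> None:
        r = self.results[name]
        pd.DataFrame(
            {
                "rank": np.arange(1, len(r.running_sum) + 1),
                "gene_id": self.ranked.index,
                "metric": self.ranked.to_numpy(),
                "running_sum": r.running_sum,
                "hit": np.isin(np.arange(len(r.running_sum)), r.hit_indices).astype(int),
            }
        ).to_csv(path, sep="\t", index=False)

    def null_histogram_tsv(self, name: str, path, bins: int = 40) -> None:
        r = self.results[name]
        counts, edges = np.histogram(r.null_es, bins=bins)
        pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        ).to_csv(path, sep="\t", index=False)


class Gsea:
    """Phenotype-permutation GSEA model.

    Parameters
    ----------
    expression
        Raw-scale (non-negative) expression matrix; class means are
        ratios of abundances.
    classes
        Sample id -> "case"/"control" labels.
    gene_sets
        Mapping of set name to member gene ids, or a
        :class:`GeneSetCollection`.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        classes: pd.Series,
        gene_sets: GeneSetCollection | dict,
    ):
        self.expression = expression
        self.classes = classes
        self.gene_sets = (
            gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else gene_sets
        )

    def fit(
        self,
        n_perm: int = 1000,
        exponent: float = DEFAULT_EXPONENT,
        seed: int = 0,
        nes_null: str = "sign_matched",
        floor: float | None = None,
        min_size: int = DEFAULT_MIN_SIZE,
        max_size: int = DEFAULT_MAX_SIZE,
    ) -> GseaResults:
        X = self.expression
        ranked = rank_metric_log2_ratio(X, self.classes, floor)
        universe = set(ranked.index)
        sets = {}
        for name, members in self.gene_sets.items():
            filtered = [g for g in members if g in universe]
            if min_size <= len(filtered) <= max_size:
                sets[name] = filtered
        if not sets:
            raise ValueError("no gene set passes size filtering")

        observed = {
            name: enrichment_score(ranked, members, exponent)
            for name, members in sets.items()
        }
        rng = np.random.default_rng(seed)
        metrics = _permuted_metrics(X, self.classes, n_perm, rng, floor)
        gene_rank = np.argsort(np.argsort(X.gene_ids.to_numpy()))
        genes = X.gene_ids.to_numpy()
        masks = {
            name: np.isin(genes, np.asarray(list(members)))
            for name, members in sets.items()
        }
        null_es = {name: np.empty(n_perm) for name in sets}
        n_genes = len(genes)
        for j in range(n_perm):
            mvec = metrics[j]
            order = np.lexsort((gene_rank, -mvec))
            absm = np.abs(mvec[order]) ** exponent
            for name, mask in masks.items():
                hit = mask[order]
                nh = hit.sum()
                sw = absm[hit].sum()
                if sw == 0:
                    steps = np.where(hit, 1.0 / nh, -1.0 / (n_genes - nh))
                else:
                    steps = np.where(hit, absm / sw, -1.0 / (n_genes - nh))
                run = np.cumsum(steps)
                null_es[name][j] = run[np.argmax(np.abs(run))]

        nes_obs, results = {}, {}
        perm_nes = {}
        for name, (es, running, hits) in observed.items():
            nes, p = normalize_es(es, null_es[name], mode=nes_null)
            nes_obs[name] = nes
            # permuted NES: each null ES normalized by the same null means
            null = null_es[name]
            pos = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
            neg = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
            with np.errstate(invalid="ignore"):
                pn = np.where(null >= 0, null / pos, null / neg)
            perm_nes[name] = pn[np.isfinite(pn)]
            results[name] = EnrichmentResult(
                name=name,
                size=len(sets[name]),
                es=es,
                nes=nes,
                nominal_p=p,
                fdr_q=np.nan,
                running_sum=running,
                hit_indices=hits,
                null_es=null,
            )
        if len(results) >= 2:
            q = gsea_fdr(pd.Series(nes_obs), perm_nes)
            for name in results:
                results[name].fdr_q = float(q[name])
        else:
            only = next(iter(results.values()))
            only.fdr_q = only.nominal_p
        return GseaResults(results=results, ranked=ranked, n_perm=n_perm)
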