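"""Synthetic expression / trait / genotype generator with planted truth.

Emulates a small post-mortem brain case/control cohort: latent-factor
co-expression modules, correlated neuropathology traits driven by module
activity, and biallelic SNVs with additive cis effects on expression.
Every draw is governed by one seed so a bundle is reproducible
byte-for-byte, and the generating structure is recorded in a
:class:`SimTruth` sidecar so downstream stages can be scored against
ground truth.

Generation model
----------------
Per-sample module factors f_m ~ N(0, 1) (centered to exact zero mean).
Gene g in module m has log2-scale expression

    baseline_g + loading_g * f_m + eps,   eps ~ N(0, noise_sd)

background genes are baseline + noise only. Values are exponentiated
(base 2) so the stored matrix is count-like and the QC log2 transform
approximately restores Gaussianity. Traits are linear combinations of the
factors plus noise; case/control labels are (by default) tied to the
first module factor through a logistic link so class-based enrichment
has signal. Planted eQTL effects multiply a gene's raw expression by
2^(beta * dosage), i.e. an additive effect of ``beta`` per alt allele on
the log2 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, TraitTable
from .vcfio import write_vcf

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "simulate_expression",
    "simulate_traits",
    "simulate_genotypes",
    "simulate_bundle",
    "write_bundle",
    "read_bundle",
]

NEUROPATH_TRAITS = ("CDR", "Braak", "NP1", "PLQ_Mn", "NTr_Sum", "NPr_Sum")
DEFAULT_TRAITS = NEUROPATH_TRAITS + ("pH", "PMI", "Age")

#: Functional-term vocabulary used for the synthetic annotation map. The
#: first module's genes draw from myelin/sphingolipid terms so the
#: keyword-based functional filter has a planted positive set.
KEYWORD_TERMS = (
    "sphingolipid metabolic process",
    "myelin sheath maintenance",
    "sphingolipid biosynthetic process",
    "myelination",
)
DECOY_TERMS = (
    "synaptic signaling",
    "oxidative phosphorylation",
    "cytoskeleton organization",
    "RNA splicing",
    "immune response",
    "metabolic process",
)


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the standard bundle: 2,000 genes x 60 samples
    (~2/3 cases, matching a ~40/20 case/control design) with four planted
    modules and 500 variants carrying 10 cis-eQTLs of effect 0.8 log2
    units per alt allele.
    """

    n_genes: int = 2000
    n_samples: int = 60
    module_sizes: tuple[int, ...] = (100, 80, 60, 50)
    factor_loading_mean: float = 1.0
    factor_loading_sd: float = 0.2
    noise_sd: float = 0.5
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    trait_module_effects: np.ndarray | None = None
    trait_noise_sd: float = 0.5
    n_variants: int = 500
    n_causal_eqtl: int = 10
    eqtl_beta: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.05
    case_fraction: float = 2.0 / 3.0
    class_link: bool = True
    class_link_strength: float = 2.0
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def effects(self) -> np.ndarray:
        """Trait-on-factor coefficient matrix (traits x modules).

        Default: the neuropathology metrics load +1 on the first module
        factor (a concordant disease block) and pH loads -0.5 on it;
        NP1 splits between the disease factor and the second module
        factor, which also drives age — emulating a clinical PCA whose
        first axis is neuropathology and whose second axis pulls NP1
        toward age. Post-mortem interval stays independent.
        """
        if self.trait_module_effects is not None:
            eff = np.asarray(self.trait_module_effects, dtype=float)
            if eff.shape != (self.n_traits, self.n_modules):
                raise InvalidConfigError(
                    f"trait_module_effects shape {eff.shape} != "
                    f"({self.n_traits}, {self.n_modules})"
                )
            return eff
        eff = np.zeros((self.n_traits, self.n_modules))
        for i, name in enumerate(self.trait_names):
            if name == "NP1" and self.n_modules > 1:
                eff[i, 0] = 0.4
                eff[i, 1] = 0.8
            elif name in NEUROPATH_TRAITS:
                eff[i, 0] = 1.0
            elif name == "pH":
                eff[i, 0] = -0.5
            elif name == "Age" and self.n_modules > 1:
                eff[i, 1] = 0.8
        return eff

    def validate(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise InvalidConfigError("every module needs at least 2 genes")
        if sum(self.module_sizes) > self.n_genes:
            raise InvalidConfigError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if not 0 < self.case_fraction < 1:
            raise InvalidConfigError("case_fraction must be in (0, 1)")
        if self.n_causal_eqtl > self.n_variants:
            raise InvalidConfigError("n_causal_eqtl exceeds n_variants")
        self.effects()


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated bundle."""

    module_labels: pd.Series           # gene -> module label, 0 = background
    factors: pd.DataFrame              # modules x samples latent scores
    trait_coeffs: pd.DataFrame         # traits x modules generating coefficients
    eqtls: list[dict] = field(default_factory=list)  # {variant, gene, beta}
    class_labels: pd.Series | None = None            # sample -> case/control
    seed: int = 0

    def module_genes(self, label: int) -> list[str]:
        return list(self.module_labels.index[self.module_labels == label])


@dataclass
class SimBundle:
    expression: ExpressionMatrix
    traits: TraitTable
    genotypes: GenotypeMatrix
    truth: SimTruth


def _rng_for(cfg: SimConfig, stream: int) -> np.random.Generator:
    # One shared seed; each sub-generator gets a fixed, documented stream.
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw the raw expression matrix and initialise the truth record."""
    cfg.validate()
    rng = _rng_for(cfg, 0)
    n, p = cfg.n_samples, cfg.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(p)], name="gene_id")
    sample_ids = pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id")

    factors = rng.standard_normal((cfg.n_modules, n))
    factors -= factors.mean(axis=1, keepdims=True)

    labels = np.zeros(p, dtype=int)
    start = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        labels[start : start + size] = m
        start += size

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=p)
    log2x = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(p, n))
    for m in range(1, cfg.n_modules + 1):
        members = labels == m
        loadings = rng.normal(
            cfg.factor_loading_mean, cfg.factor_loading_sd, size=members.sum()
        )
        log2x[members] += loadings[:, None] * factors[m - 1][None, :]

    # class labels: logistic link on the first module factor, intercept at
    # logit(case_fraction) so the expected case share is preserved
    rng_cls = _rng_for(cfg, 3)
    a = np.log(cfg.case_fraction / (1 - cfg.case_fraction))
    if cfg.class_link:
        pr = 1.0 / (1.0 + np.exp(-(a + cfg.class_link_strength * factors[0])))
    else:
        pr = np.full(n, cfg.case_fraction)
    is_case = rng_cls.random(n) < pr
    classes = pd.Series(
        np.where(is_case, "case", "control"), index=sample_ids, name="class"
    )

    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2x), index=gene_ids, columns=sample_ids)
    )
    truth = SimTruth(
        module_labels=pd.Series(labels, index=gene_ids, name="module"),
        factors=pd.DataFrame(
            factors,
            index=pd.Index(range(1, cfg.n_modules + 1), name="module"),
            columns=sample_ids,
        ),
        trait_coeffs=pd.DataFrame(
            cfg.effects(),
            index=pd.Index(cfg.trait_names, name="trait"),
            columns=range(1, cfg.n_modules + 1),
        ),
        class_labels=classes,
        seed=cfg.seed,
    )
    return expr, truth


def simulate_traits(truth: SimTruth, cfg: SimConfig) -> TraitTable:
    """Traits = trait_module_effects @ factors + Gaussian noise."""
    eff = cfg.effects()
    rng = _rng_for(cfg, 1)
    F = truth.factors.to_numpy()
    vals = eff @ F + rng.normal(0.0, cfg.trait_noise_sd, size=(cfg.n_traits, F.shape[1]))
    df = pd.DataFrame(
        vals.T, index=truth.factors.columns, columns=list(cfg.trait_names)
    )
    if truth.class_labels is not None:
        df["class"] = truth.class_labels
    return TraitTable(df)


def simulate_genotypes(truth: SimTruth, cfg: SimConfig) -> GenotypeMatrix:
    """Binomial(2, maf) dosages with missingness; plants eQTL triples in truth.

    The expression modification for planted eQTLs is applied by
    :func:`apply_eqtl_effects` (called from :func:`simulate_bundle`) using
    the pre-missingness dosages, so a missing call never erases a planted
    effect.
    """
    rng = _rng_for(cfg, 2)
    n = len(truth.factors.columns)
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_variants)
    full = rng.binomial(2, mafs[:, None], size=(cfg.n_variants, n)).astype(float)

    variant_ids = pd.Index(
        [f"rs{100000 + i}" for i in range(cfg.n_variants)], name="variant_id"
    )
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=cfg.n_variants)
    alt = np.array([rng.choice(bases[bases != r]) for r in ref])
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, cfg.n_variants + 1) * 1000,
            "ref": ref,
            "alt": alt,
        },
        index=variant_ids,
    )

    # plant effects in first-module genes: they survive connectivity-based
    # QC (so the scan sees them), and the clinical covariates proxy the
    # first module factor, so covariate adjustment exposes the genotype
    # signal — the usual rationale for covariate-adjusted eQTL scans
    module_genes = truth.module_labels.index[truth.module_labels == 1]
    genes = rng.choice(module_genes, size=cfg.n_causal_eqtl, replace=False)
    variants = rng.choice(cfg.n_variants, size=cfg.n_causal_eqtl, replace=False)
    truth.eqtls = [
        {
            "variant": variant_ids[v],
            "gene": str(g),
            "beta": cfg.eqtl_beta,
            "dosage": full[v].tolist(),
        }
        for v, g in zip(variants, genes)
    ]

    dosages = full.copy()
    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = np.nan
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=variant_ids, columns=truth.factors.columns), meta
    )


def apply_eqtl_effects(expr: ExpressionMatrix, truth: SimTruth) -> ExpressionMatrix:
    """Multiply each target gene's raw values by 2^(beta * dosage)."""
    vals = expr.values.copy()
    for q in truth.eqtls:
        dosage = np.asarray(q["dosage"], dtype=float)
        vals.loc[q["gene"]] *= np.exp2(q["beta"] * dosage)
    return ExpressionMatrix(vals)


def simulate_bundle(cfg: SimConfig | None = None) -> SimBundle:
    """Generate the full expression/trait/genotype bundle with truth."""
    cfg = cfg or SimConfig()
    expr, truth = simulate_expression(cfg)
    traits = simulate_traits(truth, cfg)
    geno = simulate_genotypes(truth, cfg)
    expr = apply_eqtl_effects(expr, truth)
    return SimBundle(expr, traits, geno, truth)


def _make_gene_sets(truth: SimTruth, n_decoys: int = 6, decoy_size: int = 100) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 4]))
    sets = {
        f"MODULE_{m}_TRUTH": truth.module_genes(m)
        for m in sorted(truth.module_labels.unique())
        if m != 0
    }
    # decoys are drawn from genes outside the class-linked first module so
    # they are genuinely null with respect to the case/control contrast
    null_genes = np.asarray(
        truth.module_labels.index[truth.module_labels != 1]
    )
    size = min(decoy_size, len(null_genes))
    for d in range(n_decoys):
        sets[f"DECOY_{d}"] = sorted(
            rng.choice(null_genes, size=size, replace=False)
        )
    return sets


def _make_annotation(truth: SimTruth) -> dict[str, list[str]]:
    """Synthetic gene -> functional-term map.

    Genes of the first planted module carry myelin/sphingolipid terms;
    other module genes get module-specific decoy terms; half of the
    background genes get a generic term, the rest stay unannotated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 5]))
    ann: dict[str, list[str]] = {}
    for gene, label in truth.module_labels.items():
        if label == 1:
            k = rng.integers(1, 3)
            ann[gene] = sorted(rng.choice(KEYWORD_TERMS, size=k, replace=False))
        elif label > 1:
            ann[gene] = [DECOY_TERMS[(label - 2) % len(DECOY_TERMS)]]
        elif rng.random() < 0.5:
            ann[gene] = [str(rng.choice(DECOY_TERMS))]
    return ann


def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Write the bundle as plain-text files; returns the path map.

    Files: expression.tsv (genes x samples), traits.csv, genotypes.vcf,
    truth.json, genesets.gmt (one truth set per module plus decoys) and
    annotation.tsv (gene <TAB> term, one term per line).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, traits, geno, truth = (
        bundle.expression,
        bundle.traits,
        bundle.genotypes,
        bundle.truth,
    )
    if not (
        list(expr.sample_ids) == list(traits.sample_ids) == list(geno.sample_ids)
    ):
        raise ValueError("sample ids inconsistent across bundle components")

    paths = {
        "expression": outdir / "expression.tsv",
        "traits": outdir / "traits.csv",
        "vcf": outdir / "genotypes.vcf",
        "truth": outdir / "truth.json",
        "gmt": outdir / "genesets.gmt",
        "annotation": outdir / "annotation.tsv",
    }
    expr.to_tsv(paths["expression"])
    traits.to_csv(paths["traits"])
    write_vcf(geno, paths["vcf"])

    truth_doc = {
        "seed": truth.seed,
        "module_labels": {str(k): int(v) for k, v in truth.module_labels.items()},
        "factors": {
            str(m): truth.factors.loc[m].tolist() for m in truth.factors.index
        },
        "trait_coeffs": {
            str(t): truth.trait_coeffs.loc[t].tolist()
            for t in truth.trait_coeffs.index
        },
        "eqtls": truth.eqtls,
        "class_labels": {str(k): str(v) for k, v in truth.class_labels.items()},
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True))

    with open(paths["gmt"], "w") as fh:
        for name, members in _make_gene_sets(truth).items():
            fh.write(name + "\tsynthetic\t" + "\t".join(members) + "\n")
    with open(paths["annotation"], "w") as fh:
        for gene, terms in _make_annotation(truth).items():
            for term in terms:
                fh.write(f"{gene}\t{term}\n")
    return paths


def read_truth(path) -> SimTruth:
    doc = json.loads(Path(path).read_text())
    labels = pd.Series(doc["module_labels"], name="module").astype(int)
    labels.index.name = "gene_id"
    classes = pd.Series(doc["class_labels"], name="class")
    classes.index.name = "sample_id"
    n_samples = len(classes)
    factors = pd.DataFrame(
        {int(m): vals for m, vals in doc["factors"].items()}
    ).T.set_axis(classes.index, axis=1)
    factors.index.name = "module"
    coeffs = pd.DataFrame(
        {t: vals for t, vals in doc["trait_coeffs"].items()}
    ).T
    coeffs.index.name = "trait"
    coeffs.columns = range(1, coeffs.shape[1] + 1)
    assert factors.shape[1] == n_samples
    return SimTruth(
        module_labels=labels,
        factors=factors.sort_index(),
        trait_coeffs=coeffs,
        eqtls=doc["eqtls"],
        class_labels=classes,
        seed=doc["seed"],
    )


def read_bundle(dirpath) -> SimBundle:
    """Load a written bundle back into memory (inverse of write_bundle)."""
    from .vcfio import read_vcf

    d = Path(dirpath)
    return SimBundle(
        expression=ExpressionMatrix.from_tsv(d / "expression.tsv"),
        traits=TraitTable.from_csv(d / "traits.csv"),
        genotypes=read_vcf(d / "genotypes.vcf"),
        truth=read_truth(d / "truth.json"),
    )
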