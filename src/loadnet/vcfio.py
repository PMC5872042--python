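"""VCF input/output for biallelic SNV dosage matrices.

Reading goes through cyvcf2; writing emits minimal, valid VCF 4.2 with GT
genotypes. Only biallelic records are accepted. Phase is not preserved:
dosages are additive alt-allele counts, missing calls are ``./.``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import GenotypeMatrix

__all__ = ["read_vcf", "write_vcf"]


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a variant-by-sample dosage matrix.

    Multi-allelic records raise; dosage is the alt-allele count from GT,
    NaN where any allele is missing.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta_rows, ids = [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gts = np.asarray(rec.genotypes, dtype=object)
        dos = np.empty(len(samples))
        for j, g in enumerate(rec.genotypes):
            a, b = g[0], g[1]
            dos[j] = np.nan if (a < 0 or b < 0) else float((a > 0) + (b > 0))
        rows.append(dos)
        ids.append(vid)
        meta_rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    dosages = pd.DataFrame(rows, index=pd.Index(ids, name="variant_id"), columns=samples)
    meta = pd.DataFrame(
        meta_rows, index=dosages.index, columns=["chrom", "pos", "ref", "alt"]
    )
    return GenotypeMatrix(dosages, meta)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as unphased GT calls (VCF 4.2)."""
    meta = geno.meta
    chroms = list(dict.fromkeys(meta["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=loadnet\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.sample_ids))
            + "\n"
        )
        dos = geno.dosages.to_numpy()
        for i, vid in enumerate(geno.variant_ids):
            m = meta.loc[vid]
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in dos[i]
            )
            fh.write(
                f"{m['chrom']}\t{int(m['pos'])}\t{vid}\t{m['ref']}\t{m['alt']}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )
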