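"""Plain-text VCF output for haplotype samples.

One record per segregating mutation in the sample, phased GT fields, and an
INFO column carrying the mutation class, per-trait effect sizes and origin
generation.  Written uncompressed so standard tools (pysam, bcftools,
VCFtools) can consume it directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .simulate import Population
from .stats import HaplotypeSample

__all__ = ["write_vcf"]

_HEADER = """\
##fileformat=VCFv4.2
##source=selfpoly
##contig=<ID=1,length={length}>
##INFO=<ID=MT,Number=1,Type=String,Description="Mutation class (neutral/trait/deleterious)">
##INFO=<ID=EFF,Number=.,Type=Float,Description="Per-trait effect sizes">
##INFO=<ID=OG,Number=1,Type=Integer,Description="Origin generation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(sample: HaplotypeSample, pop: Population, path: str | Path) -> Path:
    """Write a haplotype sample as an uncompressed, phased VCF."""
    path = Path(path)
    table = pop.table
    n_ind = len(sample.individuals)
    names = "\t".join(f"i{int(k)}" for k in sample.individuals)
    lines = [_HEADER.format(length=pop.config.L)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + names + "\n")
    ann = sample.annotations
    for k in range(len(ann)):
        mid = int(ann["id"].iloc[k])
        eff = ",".join(f"{e:.6g}" for e in np.atleast_1d(table.effects[mid]))
        info = f"MT={ann['class'].iloc[k]};EFF={eff};OG={int(table.origin[mid])}"
        gts = "\t".join(
            f"{sample.matrix[2 * i, k]}|{sample.matrix[2 * i + 1, k]}"
            for i in range(n_ind))
        lines.append(f"1\t{int(ann['position'].iloc[k]) + 1}\tm{mid}\tA\tT\t.\t"
                     f"PASS\t{info}\tGT\t{gts}\n")
    path.write_text("".join(lines))
    return path
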