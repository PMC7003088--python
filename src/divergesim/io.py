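"""Interchange formats: tidy records TSV, VCF snapshots, frequency tables.

Simulated mutations are abstract bi-allelic sites; VCF export writes the
ancestral state as REF=A and the derived allele as ALT=T with phased diploid
genotypes, positions converted to 1-based.  Sites are sorted by position;
distinct mutations at the same position become separate VCF lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import PopulationState
from .regions import RegionArchitecture

__all__ = [
    "write_records_tsv",
    "read_records_tsv",
    "write_vcf",
    "write_frequency_tsv",
]

_CLS_NAMES = {0: "noncoding", 1: "synonymous", 2: "nonsynonymous"}


def write_records_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(
    state: PopulationState,
    region: RegionArchitecture,
    path,
    pop_names: tuple[str, ...] = ("AP", "DP"),
) -> None:
    """Write the segregating sites of a population state as a phased VCF."""
    chrom = f"region_{region.region_id}"
    ncols = state.ncols
    order = np.argsort(state.pos[:ncols], kind="stable")
    samples = []
    for name, size in zip(pop_names, state.sizes):
        samples.extend(f"{name}_{i}" for i in range(size))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={region.length}>\n")
        fh.write('##INFO=<ID=CLS,Number=1,Type=String,'
                 'Description="Mutation site class">\n')
        fh.write('##INFO=<ID=EFF,Number=1,Type=Float,'
                 'Description="Additive phenotypic effect">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for col in order:
            info = (f"CLS={_CLS_NAMES[int(state.cls[col])]};"
                    f"EFF={state.eff[col]:.6g}")
            gts = []
            for g in state.G:
                a = g[0::2, col]
                b = g[1::2, col]
                gts.extend(f"{x}|{y}" for x, y in zip(a, b))
            fh.write(
                f"{chrom}\t{int(state.pos[col]) + 1}\tmut{col}\tA\tT\t.\tPASS\t"
                f"{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_frequency_tsv(
    state: PopulationState,
    path,
    pop_names: tuple[str, ...] = ("AP", "DP"),
) -> None:
    """Per-site derived-allele frequencies per deme as TSV."""
    ncols = state.ncols
    counts = state.counts()
    order = np.argsort(state.pos[:ncols], kind="stable")
    data = {
        "position": state.pos[:ncols][order],
        "site_class": [_CLS_NAMES[int(c)] for c in state.cls[:ncols][order]],
        "effect": state.eff[:ncols][order],
        "origin_gen": state.origin[:ncols][order],
    }
    for name, size, c in zip(pop_names, state.sizes, counts):
        data[f"freq_{name}"] = c[order] / (2 * size)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
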