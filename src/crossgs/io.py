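"""Plain-text file interfaces.

Genotypes travel as whitespace-delimited integer matrices (individuals x
loci, codes 0/1/2), with a phased variant of two 0/1 haplotype rows per
individual (paternal/sire-origin row first); locus maps, effect tables and
per-generation summaries are tab-separated tables.  Every table written here
carries the seed and a config hash in ``#`` header comments.
"""

from __future__ import annotations

import gzip
from typing import Optional

import numpy as np
import pandas as pd

from .genome import QTL, SNP, GenomeMap, Population
from .mcmc import ModelFit
from .trait import TraitArchitecture


def _open(path: str, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_genotype_matrix(path: str, pop: Population,
                          loci: Optional[np.ndarray] = None,
                          phased: bool = False) -> None:
    mat = (pop.haplotypes if loci is None else pop.haplotypes[:, loci]) \
        if phased else pop.genotypes(loci)
    with _open(path, "w") as fh:
        np.savetxt(fh, mat, fmt="%d")


def read_genotype_matrix(path: str, phased: bool = False) -> Population:
    with _open(path, "r") as fh:
        mat = np.loadtxt(fh, dtype=np.int8, ndmin=2)
    if phased:
        if mat.shape[0] % 2:
            raise ValueError("phased matrix needs two rows per individual")
        if mat.max(initial=0) > 1:
            raise ValueError("phased matrix must contain 0/1 haplotypes")
        return Population(haplotypes=mat)
    hap = np.zeros((2 * mat.shape[0], mat.shape[1]), np.int8)
    hap[0::2] = (mat >= 1)
    hap[1::2] = (mat == 2)   # arbitrary but consistent phase for 0/1/2 input
    return Population(haplotypes=hap)


def write_phenotypes(path: str, y: np.ndarray) -> None:
    np.savetxt(path, np.asarray(y, float), fmt="%.10g")


def read_phenotypes(path: str) -> np.ndarray:
    return np.loadtxt(path, dtype=float, ndmin=1)


def write_map(path: str, gmap: GenomeMap) -> None:
    df = pd.DataFrame({
        "chromosome": gmap.chrom,
        "position_morgan": gmap.positions,
        "role": np.where(gmap.role == QTL, "QTL", "SNP"),
    })
    df.to_csv(path, sep="\t", index=False)


def read_map(path: str, chrom_length: float = 1.0,
             mutation_rate: float = 2.5e-5,
             interference: int = 4) -> GenomeMap:
    df = pd.read_csv(path, sep="\t")
    role = np.where(df["role"].to_numpy() == "QTL", QTL, SNP).astype(np.int8)
    chrom = df["chromosome"].to_numpy(np.int32)
    return GenomeMap(n_chromosomes=int(chrom.max()) + 1,
                     chrom_length=chrom_length, chrom=chrom,
                     positions=df["position_morgan"].to_numpy(float),
                     role=role, mutation_rate=mutation_rate,
                     interference=interference)


def write_trait_table(path: str, gmap: GenomeMap,
                      arch: TraitArchitecture) -> None:
    qtl = gmap.qtl_indices
    pd.DataFrame({
        "qtl_index": np.arange(arch.n_qtl),
        "chromosome": gmap.chrom[qtl],
        "position_morgan": gmap.positions[qtl],
        "a": arch.a,
        "d": arch.d,
    }).to_csv(path, sep="\t", index=False)


def read_trait_table(path: str) -> TraitArchitecture:
    df = pd.read_csv(path, sep="\t")
    return TraitArchitecture(a=df["a"].to_numpy(float),
                             d=df["d"].to_numpy(float))


def write_effect_table(path: str, fit: ModelFit,
                       header: Optional[dict] = None) -> None:
    rows = []
    for cls, eff in fit.effects.items():
        incl = fit.inclusion[cls]
        for j in range(eff.shape[0]):
            rows.append((j, cls, eff[j], incl[j]))
    df = pd.DataFrame(rows, columns=["snp", "effect_class", "estimate",
                                     "inclusion_frequency"])
    write_table(path, df, header)


def write_nonzero_trace(path: str, fit: ModelFit,
                        header: Optional[dict] = None) -> None:
    df = pd.DataFrame(fit.nonzero_trace)
    df.insert(0, "iteration", np.arange(len(df)))
    write_table(path, df, header)


def write_table(path: str, df: pd.DataFrame,
                header: Optional[dict] = None) -> None:
    with _open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
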