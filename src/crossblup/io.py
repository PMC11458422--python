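"""Plain-text interchange formats.

Pedigree CSV (id,sire,dam,sex,generation,population; 0 = unknown parent),
PLINK .raw-style allele-count genotype tables with an optional map file,
phenotype CSV, solutions CSV, and a symmetric-coordinate matrix dump for
debugging relationship matrices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

POP_NAMES = np.array(["A", "B", "AB", "HIST"])
SEX_NAMES = np.array(["M", "F"])


def pedigree_frame(sire, dam, sex, generation, population) -> pd.DataFrame:
    n = len(sire)
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "sire": np.asarray(sire),
        "dam": np.asarray(dam),
        "sex": SEX_NAMES[np.asarray(sex)],
        "generation": np.asarray(generation),
        "population": POP_NAMES[np.asarray(population)],
    })


def write_pedigree(path, sire, dam, sex, generation, population) -> None:
    pedigree_frame(sire, dam, sex, generation, population).to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"id", "sire", "dam", "sex", "generation", "population"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file lacks columns {sorted(missing)}")
    return df


def write_raw_genotypes(path, ids, counts, sex=None, phenotype=None,
                        locus_names=None) -> None:
    """PLINK .raw-compatible layout: FID IID PAT MAT SEX PHENOTYPE then one
    allele-count column per locus."""
    counts = np.asarray(counts)
    n, m = counts.shape
    if locus_names is None:
        locus_names = [f"snp{j + 1}" for j in range(m)]
    ids = np.asarray(ids)
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE", *locus_names]
    body = pd.DataFrame(counts, columns=locus_names)
    meta = pd.DataFrame({
        "FID": np.ones(n, dtype=int),
        "IID": ids,
        "PAT": np.zeros(n, dtype=int),
        "MAT": np.zeros(n, dtype=int),
        "SEX": (np.asarray(sex) + 1) if sex is not None else np.zeros(n, int),
        "PHENOTYPE": phenotype if phenotype is not None else np.full(n, -9),
    })
    pd.concat([meta, body], axis=1).to_csv(path, sep=" ", index=False,
                                           columns=header)


def read_raw_genotypes(path) -> tuple[np.ndarray, np.ndarray, list]:
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    loci = [c for c in df.columns if c not in meta_cols]
    return df["IID"].to_numpy(), df[loci].to_numpy(dtype=np.int8), loci


def write_map(path, genome) -> None:
    pd.DataFrame({
        "chrom": genome.chrom + 1,
        "locus": [f"{'qtl' if q else 'snp'}{j + 1}"
                  for j, q in enumerate(genome.is_qtl)],
        "position_cM": genome.positions_cm,
    }).to_csv(path, index=False)


def write_solutions(path, results: pd.DataFrame) -> None:
    results.to_csv(path, index=False)


def write_symmetric_coo(path, mat, ids=None) -> None:
    """Lower triangle of a symmetric matrix as 'i j value' text; the
    optional sidecar '<path>.ids' maps row numbers to animal ids."""
    m = sp.coo_matrix(mat)
    keep = m.row >= m.col
    df = pd.DataFrame({"i": m.row[keep] + 1, "j": m.col[keep] + 1,
                       "value": m.data[keep]})
    df.sort_values(["i", "j"]).to_csv(path, sep=" ", index=False, header=False)
    if ids is not None:
        Path(str(path) + ".ids").write_text(
            "\n".join(str(i) for i in ids) + "\n")
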