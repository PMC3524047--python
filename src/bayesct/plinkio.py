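"""Text PLINK (.ped/.map) and phenotype CSV round-tripping.

Alleles are written as A/B letters (B = founder minor/top-strand allele),
missing calls as "0 0". The .map carries chromosome, SNP id, a zero
genetic distance and the 1-based bp position. Phenotype tables are plain
CSV with animal_id, sire_id, status (1 = control, 2 = case) and factor
columns; truth records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import MISSING, GenotypeMatrix

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_phenotypes",
    "read_phenotypes",
    "write_truth",
    "read_truth",
]

_GENO_TO_ALLELES = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}


def write_ped_map(
    genotypes: GenotypeMatrix,
    snp_map: pd.DataFrame,
    phenotypes: pd.DataFrame,
    prefix: str | Path,
) -> None:
    prefix = Path(prefix)
    m = snp_map.set_index("snp").loc[genotypes.snp_ids]
    with open(prefix.with_suffix(".map"), "w") as fh:
        for snp, row in m.iterrows():
            fh.write(f"{row['chrom']}\t{snp}\t0\t{row['pos']}\n")
    ph = phenotypes.set_index("animal_id")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(genotypes.animal_ids):
            rec = ph.loc[animal]
            sex = {"M": "1", "F": "2"}.get(str(rec.get("sex", "0")), "0")
            alleles = " ".join(
                _GENO_TO_ALLELES[int(c)] for c in genotypes.calls[i]
            )
            fh.write(
                f"FAM {animal} {rec.get('sire_id', '0')} 0 {sex} "
                f"{int(rec['status'])} {alleles}\n"
            )


def read_ped_map(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"),
        sep="\t",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str},
    )[["snp", "chrom", "pos"]]
    animals, sires, status, rows = [], [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            animals.append(parts[1])
            sires.append(parts[2])
            status.append(int(parts[5]))
            alleles = parts[6:]
            calls = np.empty(len(alleles) // 2, dtype=np.int8)
            for j in range(calls.size):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    calls[j] = MISSING
                else:
                    calls[j] = (a == "B") + (b == "B")
            rows.append(calls)
    gm = GenotypeMatrix(
        animal_ids=np.array(animals, dtype=str),
        snp_ids=snp_map["snp"].to_numpy().astype(str),
        calls=np.vstack(rows),
    )
    pheno = pd.DataFrame(
        {"animal_id": animals, "sire_id": sires, "status": status}
    )
    return gm, snp_map, pheno


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
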