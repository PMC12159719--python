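"""Readers and writers for the tabular interchange formats.

Genotypes travel as TSV (``genotype_id`` + one column per SNP id),
phenotypes as long-format CSV (``genotype_id,location,year,trait,value``).
All numeric output is written in full double precision with a
locale-independent decimal point (pandas defaults).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    PHENOTYPE_COLUMNS,
    MarkerMatrix,
    BLUETable,
    ValidationError,
    validate_phenotypes,
)


def write_genotypes(markers: MarkerMatrix, path: str | Path) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> MarkerMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if "genotype_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'genotype_id' column")
    snp_ids = [c for c in df.columns if c != "genotype_id"]
    if not snp_ids:
        raise ValidationError(f"{path}: no SNP columns")
    genotype_ids = df["genotype_id"].astype(str).tolist()
    raw = df[snp_ids].to_numpy()
    flo = raw.astype(float)
    if not np.all(np.isfinite(flo)):
        i, j = np.argwhere(~np.isfinite(flo))[0]
        raise ValidationError(
            f"{path}: missing dosage at genotype {genotype_ids[i]!r}, snp {snp_ids[j]!r}"
        )
    if not np.allclose(flo, np.round(flo)):
        i, j = np.argwhere(~np.isclose(flo, np.round(flo)))[0]
        raise ValidationError(
            f"{path}: non-integer dosage {flo[i, j]!r} at genotype "
            f"{genotype_ids[i]!r}, snp {snp_ids[j]!r}"
        )
    # MarkerMatrix rejects values outside {0,1,2}, naming the cell
    return MarkerMatrix(genotype_ids, snp_ids, flo.astype(np.int64))


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.loc[:, list(PHENOTYPE_COLUMNS)].to_csv(path, index=False)


def read_phenotypes(
    path: str | Path, markers: MarkerMatrix | None = None
) -> pd.DataFrame:
    """Read and validate a phenotype CSV.

    If ``markers`` is given, every phenotype record must reference a
    genotype present in the marker matrix (orphans are listed in the error).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = validate_phenotypes(pd.read_csv(path))
    if markers is not None:
        known = set(markers.genotype_ids)
        orphans = sorted(set(df["genotype_id"]) - known)
        if orphans:
            raise ValidationError(
                f"{path}: phenotype records reference genotypes absent from the "
                f"marker matrix: {orphans[:10]}"
                + ("..." if len(orphans) > 10 else "")
            )
    return df


def write_blue_table(blues: BLUETable, blues_path: str | Path,
                     components_path: str | Path) -> None:
    blues.blues.to_csv(blues_path, index=False)
    blues.components.to_csv(components_path, index=False)


def read_blue_table(blues_path: str | Path, components_path: str | Path) -> BLUETable:
    return BLUETable(pd.read_csv(blues_path), pd.read_csv(components_path))


def write_selected_snps(snp_ids: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(snp_ids) + "\n")


def read_selected_snps(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_ground_truth(truth, outdir: str | Path) -> None:
    """Ground-truth sidecar CSVs for parameter-recovery analyses."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        truth.true_genetic_values, index=truth.genotype_ids, columns=truth.locations
    ).rename_axis("genotype_id").to_csv(outdir / "true_genetic_values.csv")
    pd.DataFrame(
        truth.location_effects.T, columns=truth.locations
    ).to_csv(outdir / "location_effects.csv", index=False)
    pd.DataFrame(
        {"location": truth.locations, "location_mean": truth.location_means}
    ).to_csv(outdir / "location_means.csv", index=False)
    pd.DataFrame(
        truth.year_effects, index=truth.locations
    ).rename_axis("location").to_csv(outdir / "year_effects.csv")
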