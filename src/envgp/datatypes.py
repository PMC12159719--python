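"""Core data containers shared across the pipeline.

Tabular data (phenotype records, BLUEs, cross-validation results) live in
pandas DataFrames with fixed schemas; the marker matrix and modeling
datasets get thin dataclass wrappers so invariants (unique ids, 0/1/2
dosages, aligned blocks) are checked once at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a long-format phenotype table.
PHENOTYPE_COLUMNS = ("genotype_id", "location", "year", "trait", "value")


class ValidationError(ValueError):
    """Raised when an input table violates its declared schema."""


@dataclass
class MarkerMatrix:
    """Genotypes x SNPs dosage matrix.

    Dosages count copies of the *major* allele (0, 1 or 2), the coding used
    throughout for X in the linear model y = X beta + eps.
    """

    genotype_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.genotype_ids = list(self.genotype_ids)
        self.snp_ids = list(self.snp_ids)
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n != len(self.genotype_ids) or m != len(self.snp_ids):
            raise ValidationError(
                f"dosage matrix is {self.dosages.shape} but there are "
                f"{len(self.genotype_ids)} genotype ids and {len(self.snp_ids)} snp ids"
            )
        if len(set(self.genotype_ids)) != n:
            raise ValidationError("duplicate genotype ids")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("duplicate snp ids")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]!r} at genotype "
                f"{self.genotype_ids[i]!r}, snp {self.snp_ids[j]!r} is not in {{0,1,2}}"
            )
        self.dosages = self.dosages.astype(np.int64)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, min(f, 1-f) with f = sum/2n."""
        f = self.dosages.sum(axis=0) / (2.0 * self.n_genotypes)
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, snp_ids: list[str]) -> "MarkerMatrix":
        idx = {s: j for j, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown snp ids: {missing[:5]}")
        cols = [idx[s] for s in snp_ids]
        return MarkerMatrix(self.genotype_ids, list(snp_ids), self.dosages[:, cols])

    def rows_for(self, genotype_ids: list[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.genotype_ids)}
        missing = [g for g in genotype_ids if g not in idx]
        if missing:
            raise KeyError(f"unknown genotype ids: {missing[:5]}")
        return self.dosages[[idx[g] for g in genotype_ids], :]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.insert(0, "genotype_id", self.genotype_ids)
        return df


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table and normalize dtypes."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    out = df.loc[:, list(PHENOTYPE_COLUMNS)].copy()
    if out["value"].isna().any():
        rows = out.index[out["value"].isna()].tolist()
        raise ValidationError(f"missing phenotype values at rows {rows[:5]}")
    out["genotype_id"] = out["genotype_id"].astype(str)
    out["location"] = out["location"].astype(str)
    out["trait"] = out["trait"].astype(str)
    out["year"] = out["year"].astype(int)
    out["value"] = out["value"].astype(float)
    return out


@dataclass
class BLUETable:
    """Per-location genotype BLUEs with location-level variance components.

    ``blues`` columns: location, genotype_id, trait, blue.
    ``components`` columns: location, trait, sigma_g2, sigma_i2, sigma_e2,
    h2, phenotypic_variance, n_genotypes, n_years.
    """

    blues: pd.DataFrame
    components: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.blues.duplicated(subset=["location", "genotype_id", "trait"])
        if dup.any():
            raise ValidationError("duplicate (location, genotype, trait) BLUEs")

    def for_trait(self, trait: str) -> "BLUETable":
        return BLUETable(
            self.blues[self.blues["trait"] == trait].reset_index(drop=True),
            self.components[self.components["trait"] == trait].reset_index(drop=True),
        )


@dataclass
class LocationBlock:
    """Aligned features/responses for one location."""

    genotype_ids: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y) or self.X.shape[0] != len(self.genotype_ids):
            raise ValidationError("location block rows misaligned")


@dataclass
class ModelingDataset:
    """Per-location modeling blocks for one trait on the selected SNPs."""

    trait: str
    selected_snp_ids: list[str]
    blocks: dict[str, LocationBlock] = field(default_factory=dict)

    @property
    def locations(self) -> list[str]:
        return sorted(self.blocks)

    def training_locations(self, test_location: str) -> list[str]:
        if test_location not in self.blocks:
            raise KeyError(f"unknown location {test_location!r}")
        return [l for l in self.locations if l != test_location]

    def stacked(self, locations: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Row-concatenation of the given location blocks."""
        X = np.vstack([self.blocks[l].X for l in locations])
        y = np.concatenate([self.blocks[l].y for l in locations])
        return X, y
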