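"""Marker preprocessing: MAF filtering and PCA-based SNP selection.

PCA feature selection ranks principal components of the (column-centered)
dosage matrix by eigenvalue and, for each of the top components in turn,
keeps the single SNP carrying the largest absolute loading that has not
already been selected (walking down that component's |loading| ranking on
collision).  Ties are broken by lexicographic SNP id so selection is
deterministic and invariant to column order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import BLUETable, LocationBlock, MarkerMatrix, ModelingDataset


def filter_maf(markers: MarkerMatrix, threshold: float = 0.05) -> MarkerMatrix:
    """Retain SNPs with minor allele frequency strictly above ``threshold``."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    keep = markers.maf() > threshold
    if not keep.any():
        raise ValueError(
            f"MAF filter at {threshold} removed all {markers.n_snps} SNPs"
        )
    kept_ids = [s for s, k in zip(markers.snp_ids, keep) if k]
    return MarkerMatrix(markers.genotype_ids, kept_ids, markers.dosages[:, keep])


def pca_feature_select(
    markers: MarkerMatrix, n_components: int | None = None
) -> list[str]:
    """Select one SNP per top principal component, by |loading|.

    ``n_components`` defaults to ``min(n_genotypes - 1, n_snps)`` — the
    number of informative components is limited by the number of
    observations.
    """
    n, m = markers.n_genotypes, markers.n_snps
    if n_components is None:
        n_components = min(max(n - 1, 1), m)
    limit = min(n, m)
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components = {n_components} outside [1, min(n_obs, n_snps) = {limit}]"
        )
    X = markers.dosages.astype(float)
    Xc = X - X.mean(axis=0)
    # eigenvectors of the SNP covariance, via SVD of the centered matrix
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    order = np.argsort(-svals, kind="stable")  # descending eigenvalue
    Vt = Vt[order]

    snp_ids = np.asarray(markers.snp_ids)
    selected: list[str] = []
    taken: set[str] = set()
    for comp in range(n_components):
        # rank SNPs by |loading| descending, lexicographic snp_id on ties;
        # loadings rounded so float-noise-level ties break deterministically
        loadings = np.round(np.abs(Vt[comp]), 10)
        rank = sorted(range(m), key=lambda j: (-loadings[j], snp_ids[j]))
        for j in rank:
            sid = str(snp_ids[j])
            if sid not in taken:
                selected.append(sid)
                taken.add(sid)
                break
    return selected


def assemble_dataset(
    markers: MarkerMatrix,
    blues: BLUETable,
    trait: str,
    selected_snps: list[str],
) -> ModelingDataset:
    """Join BLUEs to selected-SNP features, one aligned block per location.

    Locations with fewer than two genotype BLUEs are dropped with a
    warning — a single observation can neither train nor score a model.
    """
    table = blues.blues[blues.blues["trait"] == trait]
    if table.empty:
        raise KeyError(f"trait {trait!r} absent from the BLUE table")
    sub = markers.subset_snps(selected_snps)
    blocks: dict[str, LocationBlock] = {}
    for loc, grp in table.groupby("location"):
        if len(grp) < 2:
            warnings.warn(
                f"location {loc!r} has {len(grp)} BLUE(s); dropped from the "
                f"modeling dataset",
                stacklevel=2,
            )
            continue
        gids = grp["genotype_id"].tolist()
        blocks[str(loc)] = LocationBlock(
            genotype_ids=gids,
            X=sub.rows_for(gids).astype(float),
            y=grp["blue"].to_numpy(dtype=float),
        )
    return ModelingDataset(trait=trait, selected_snp_ids=list(selected_snps),
                           blocks=blocks)
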