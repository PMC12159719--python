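"""GGE biplot geometry from per-location BLUEs.

The genotype x environment cell-mean matrix (one BLUE per cell) is
environment-centered — each column has its mean over genotypes removed —
so the singular value decomposition of the centered matrix captures
genotype main effects plus genotype-by-environment interaction (the "GGE"
part of y_ij = u + a_i + B_j + phi_ij).  Under environment-focused
singular value partitioning (SVP) the environment scores are V S and the
genotype scores U; environment vector length then reads as
discriminativeness (genotypic variance elicited) and the angle between two
environment vectors as their genetic correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BLUETable, ValidationError


@dataclass
class GGEResult:
    cell_matrix: pd.DataFrame         # genotypes x environments, mean-filled
    centered: pd.DataFrame            # environment-centered cells
    U: np.ndarray
    singular_values: np.ndarray
    Vt: np.ndarray
    svp: str                          # "environment" | "genotype"
    genotype_scores: pd.DataFrame     # first 2 components under the SVP
    environment_scores: pd.DataFrame  # first 2 components under the SVP
    pc_variance_fractions: np.ndarray
    fill_fraction: float

    @property
    def environments(self) -> list[str]:
        return list(self.centered.columns)

    def environment_scores_full(self) -> np.ndarray:
        """All-component environment scores V S (environment-focused)."""
        return self.Vt.T * self.singular_values


def build_ge_matrix(
    blues: BLUETable, trait: str
) -> tuple[pd.DataFrame, float]:
    """Genotype x environment cell matrix of BLUEs.

    Environments with fewer than two observed genotypes are dropped with a
    warning.  Missing cells (genotype not grown in an environment) are
    filled with that environment's observed mean — equivalently zero after
    centering — and the fill fraction is returned alongside.
    """
    table = blues.blues[blues.blues["trait"] == trait]
    if table.empty:
        raise KeyError(f"trait {trait!r} absent from BLUE table")
    if table.duplicated(subset=["location", "genotype_id"]).any():
        raise ValidationError("duplicate (genotype, environment) BLUEs")
    cells = table.pivot(index="genotype_id", columns="location", values="blue")
    thin = [c for c in cells.columns if cells[c].notna().sum() < 2]
    if thin:
        warnings.warn(f"environments dropped (< 2 observed genotypes): {thin}",
                      stacklevel=2)
        cells = cells.drop(columns=thin)
    if cells.shape[0] < 2 or cells.shape[1] < 2:
        raise ValueError("GGE needs >= 2 genotypes and >= 2 environments")
    fill_fraction = float(cells.isna().to_numpy().mean())
    cells = cells.fillna(cells.mean(axis=0))
    cells.columns.name = None
    cells.index.name = "genotype_id"
    return cells, fill_fraction


def center_environments(cell_matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each environment column's mean over genotypes."""
    if cell_matrix.isna().any().any():
        raise ValueError("centering requires a complete (filled) cell matrix")
    return cell_matrix - cell_matrix.mean(axis=0)


def gge_svd(
    centered: pd.DataFrame, svp: str = "environment", fill_fraction: float = 0.0
) -> GGEResult:
    """SVD of the centered matrix with singular value partitioning.

    Sign convention: each component is flipped so its largest-magnitude
    environment loading is positive (resolves the SVD sign ambiguity
    deterministically).
    """
    if svp not in ("environment", "genotype"):
        raise ValueError("svp must be 'environment' or 'genotype'")
    M = centered.to_numpy(dtype=float)
    if min(M.shape) < 2:
        raise ValueError("centered matrix must be at least 2 x 2")
    if not np.any(M):
        raise ValueError("all-zero centered matrix has no GGE structure")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    for k in range(len(s)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    fractions = s**2 / np.sum(s**2)

    env_full = Vt.T * s                     # environment-focused, all comps
    if svp == "environment":
        env2, gen2 = env_full[:, :2], U[:, :2]
    else:
        env2, gen2 = Vt.T[:, :2], (U * s)[:, :2]
    env_scores = pd.DataFrame(env2, index=centered.columns, columns=["pc1", "pc2"])
    gen_scores = pd.DataFrame(gen2, index=centered.index, columns=["pc1", "pc2"])
    return GGEResult(
        cell_matrix=centered,  # run_gge overwrites with the raw cell means
        centered=centered,
        U=U, singular_values=s, Vt=Vt, svp=svp,
        genotype_scores=gen_scores, environment_scores=env_scores,
        pc_variance_fractions=fractions, fill_fraction=fill_fraction,
    )


def env_vector_stats(result: GGEResult) -> tuple[pd.Series, pd.DataFrame]:
    """Vector lengths and pairwise cosines of the 2-component env scores.

    Length = discriminativeness read-out; cosine of the angle between two
    environment vectors approximates their genetic correlation.  Pairs
    involving a zero-length vector get NaN cosines.
    """
    scores = result.environment_scores.to_numpy()
    lengths = pd.Series(np.linalg.norm(scores, axis=1),
                        index=result.environments, name="vector_length")
    norms = lengths.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (scores @ scores.T) / np.outer(norms, norms)
    cos[~np.isfinite(cos)] = np.nan
    np.fill_diagonal(cos, 1.0)
    cosines = pd.DataFrame(cos, index=result.environments,
                           columns=result.environments)
    if (norms == 0).any():
        zero = lengths.index[norms == 0].tolist()
        warnings.warn(f"zero-length environment vectors: {zero}; cosines flagged",
                      stacklevel=2)
        for z in zero:
            cosines.loc[z, :] = np.nan
            cosines.loc[:, z] = np.nan
    return lengths, cosines


def run_gge(blues: BLUETable, trait: str, svp: str = "environment") -> GGEResult:
    """Cell matrix -> centering -> SVD, in one call."""
    cells, fill = build_ge_matrix(blues, trait)
    centered = center_environments(cells)
    result = gge_svd(centered, svp=svp, fill_fraction=fill)
    result.cell_matrix = cells
    return result


def plot_biplot(result: GGEResult, path: str) -> None:
    """Two-component biplot with PC variance fractions in the axis labels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    gen = result.genotype_scores
    env = result.environment_scores
    ax.scatter(gen["pc1"], gen["pc2"], s=8, alpha=0.4, label="genotypes")
    for name, row in env.iterrows():
        ax.annotate("", xy=(row["pc1"], row["pc2"]), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:red"))
        ax.annotate(name, (row["pc1"], row["pc2"]), color="tab:red", fontsize=9)
    f1, f2 = result.pc_variance_fractions[:2] * 100
    ax.set_xlabel(f"PC1 ({f1:.1f}%)")
    ax.set_ylabel(f"PC2 ({f2:.1f}%)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_title(f"GGE biplot ({result.svp}-focused SVP)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
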