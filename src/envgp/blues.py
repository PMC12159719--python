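"""Per-location BLUEs, variance components and broad-sense heritability.

Within one location, phenotype records over years are modeled as

    Y_ik = mu + G_i + S_k + e_ik

with genotype fixed and year random.  Genotype BLUEs are the adjusted
means from that model (REML).  Because a fixed effect carries no variance
component, the genotypic variance sg2 comes from a companion fit of the
same records with genotype *random* (year random, REML); broad-sense
heritability is then

    H2 = sg2 / (sg2 + si2 + se2)

with si2 the year-within-location variance and se2 the residual variance.
Single-year locations set si2 = 0 and fit genotype + residual only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .datatypes import BLUETable

_ZERO_TOL = 1e-12


class FitError(RuntimeError):
    """REML fit failed to converge; carries optimizer diagnostics."""


def heritability(sigma_g2: float, sigma_i2: float, sigma_e2: float) -> float:
    """Broad-sense heritability sg2 / (sg2 + si2 + se2)."""
    if min(sigma_g2, sigma_i2, sigma_e2) < 0:
        raise ValueError("variance components must be nonnegative")
    total = sigma_g2 + sigma_i2 + sigma_e2
    if total == 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return sigma_g2 / total


def phenotypic_variance(blues: np.ndarray) -> float:
    """Sample variance (n-1 denominator) of the genotype BLUEs."""
    blues = np.asarray(blues, dtype=float)
    if blues.size < 2:
        raise ValueError("phenotypic variance needs at least 2 BLUEs")
    return float(np.var(blues, ddof=1))


def _adjusted_means_ols(df: pd.DataFrame) -> tuple[pd.Series, float]:
    """Two-way fixed-effect adjusted means (min-norm least squares).

    Genotype in cell-means coding, year in sum-to-zero coding, so each
    genotype coefficient is its mean adjusted to the average year.  Exact
    on balanced data; used for single-year and (near-)noise-free records
    where the mixed model degenerates.  Also returns the residual sum of
    squares of the two-way fit.
    """
    genotypes = sorted(df["genotype_id"].unique())
    years = sorted(df["year"].unique())
    g_idx = {g: i for i, g in enumerate(genotypes)}
    n_g, n_y = len(genotypes), len(years)
    D = np.zeros((len(df), n_g + max(n_y - 1, 0)))
    rows = np.arange(len(df))
    D[rows, df["genotype_id"].map(g_idx).to_numpy()] = 1.0
    if n_y > 1:
        y_idx = {y: k for k, y in enumerate(years)}
        ycol = df["year"].map(y_idx).to_numpy()
        for k in range(n_y - 1):
            D[rows[ycol == k], n_g + k] = 1.0
            D[rows[ycol == n_y - 1], n_g + k] -= 1.0
    y = df["value"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid_ss = float(np.sum((y - D @ coef) ** 2))
    return pd.Series(coef[:n_g], index=genotypes), resid_ss


def _fit_mixed(model: sm.MixedLM, label: str):
    """Fit with REML, trying a few optimizers before declaring failure."""
    last = None
    for method in ("lbfgs", "cg", "powell"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            # statsmodels flags boundary (zero-variance) solutions as singular
            warnings.filterwarnings("ignore", message=".*covariance.*singular.*")
            warnings.filterwarnings("ignore", message=".*covariance is singular.*")
            try:
                res = model.fit(reml=True, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
                last = exc
                continue
        if res.converged and np.all(np.isfinite(res.params)):
            return res
        last = res
    raise FitError(
        f"{label}: REML did not converge after trying lbfgs/cg/powell; "
        f"last result: {last}"
    )


def _blues_mixed(df: pd.DataFrame) -> pd.Series:
    genotypes = sorted(df["genotype_id"].unique())
    exog = pd.get_dummies(
        pd.Categorical(df["genotype_id"], categories=genotypes), dtype=float
    ).to_numpy()
    model = sm.MixedLM(
        df["value"].to_numpy(dtype=float), exog, groups=df["year"].to_numpy()
    )
    res = _fit_mixed(model, "BLUE model (fixed genotype, random year)")
    return pd.Series(np.asarray(res.fe_params)[: len(genotypes)], index=genotypes)


def _components_mixed(df: pd.DataFrame, multi_year: bool) -> tuple[float, float, float]:
    # fit on the standardized response so estimates (hence h2) are exactly
    # scale-equivariant, then map variances back to the original scale
    scale = float(df["value"].std(ddof=1))
    if scale <= 0 or not np.isfinite(scale):
        scale = 1.0
    data = df.assign(_all=1, value=df["value"] / scale)
    vcf = {"genotype": "0 + C(genotype_id)"}
    if multi_year:
        vcf["year"] = "0 + C(year)"
    model = sm.MixedLM.from_formula(
        "value ~ 1", groups="_all", vc_formula=vcf, re_formula="0", data=data
    )
    res = _fit_mixed(model, "variance-component model (random genotype/year)")
    comp = dict(zip(model.exog_vc.names, np.asarray(res.vcomp, dtype=float)))
    s2 = scale ** 2
    sigma_g2 = comp.get("genotype", 0.0) * s2
    sigma_i2 = (comp.get("year", 0.0) * s2) if multi_year else 0.0
    sigma_e2 = float(res.scale) * s2
    out = []
    for name, v in (("sigma_g2", sigma_g2), ("sigma_i2", sigma_i2),
                    ("sigma_e2", sigma_e2)):
        if v < 0:
            warnings.warn(f"{name} estimated negative ({v:.3g}); truncated at 0",
                          stacklevel=3)
            v = 0.0
        out.append(float(v))
    return tuple(out)


def fit_location_model(
    records: pd.DataFrame, components: bool = True
) -> tuple[pd.Series, dict[str, float]]:
    """BLUEs and variance components for one location x trait slice.

    ``records`` needs columns genotype_id, year, value.  Returns the
    genotype-indexed BLUE series (adjusted-mean scale) and a dict with
    sigma_g2, sigma_i2, sigma_e2, h2, n_genotypes, n_years (empty h2 keys
    when ``components`` is False).
    """
    df = records.loc[:, ["genotype_id", "year", "value"]].copy()
    n_g = df["genotype_id"].nunique()
    if n_g < 2:
        raise ValueError(f"need >= 2 genotypes, got {n_g}")
    n_y = df["year"].nunique()
    y = df["value"].to_numpy(dtype=float)
    total_ss = float(np.sum((y - y.mean()) ** 2))

    # degenerate cases where REML has nothing to estimate
    ols_blues, resid_ss = _adjusted_means_ols(df)
    degenerate = total_ss < _ZERO_TOL or resid_ss < _ZERO_TOL * max(total_ss, 1.0)

    if n_y == 1 or degenerate:
        blues = ols_blues
    else:
        blues = _blues_mixed(df)

    info: dict[str, float] = {"n_genotypes": n_g, "n_years": n_y}
    if components:
        if total_ss < _ZERO_TOL:
            sg2 = si2 = se2 = 0.0
        else:
            sg2, si2, se2 = _components_mixed(df, multi_year=n_y > 1)
        info.update(sigma_g2=sg2, sigma_i2=si2, sigma_e2=se2)
        if sg2 + si2 + se2 > 0:
            info["h2"] = heritability(sg2, si2, se2)
        else:
            info["h2"] = float("nan")
    return blues, info


def compute_blues(
    phenotypes: pd.DataFrame,
    traits: list[str] | None = None,
    components: bool = True,
) -> BLUETable:
    """Fit the location model for every (trait, location) slice."""
    if traits is None:
        traits = sorted(phenotypes["trait"].unique())
    blue_rows, comp_rows = [], []
    for trait in traits:
        sub = phenotypes[phenotypes["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} absent from phenotype table")
        for loc in sorted(sub["location"].unique()):
            slice_ = sub[sub["location"] == loc]
            if slice_["genotype_id"].nunique() < 2:
                warnings.warn(
                    f"location {loc!r} (trait {trait!r}) has < 2 genotypes; skipped",
                    stacklevel=2,
                )
                continue
            try:
                blues, info = fit_location_model(slice_, components=components)
            except FitError as exc:
                warnings.warn(
                    f"variance components unavailable for location {loc!r} "
                    f"(trait {trait!r}): {exc}; reporting BLUEs only",
                    stacklevel=2,
                )
                blues, info = fit_location_model(slice_, components=False)
            for g, b in blues.items():
                blue_rows.append((loc, g, trait, float(b)))
            row = {"location": loc, "trait": trait,
                   "phenotypic_variance": phenotypic_variance(blues.to_numpy()),
                   "n_genotypes": int(info["n_genotypes"]),
                   "n_years": int(info["n_years"])}
            for key in ("sigma_g2", "sigma_i2", "sigma_e2", "h2"):
                row[key] = info.get(key, float("nan"))
            comp_rows.append(row)
    blues_df = pd.DataFrame(blue_rows,
                            columns=["location", "genotype_id", "trait", "blue"])
    comp_df = pd.DataFrame(
        comp_rows,
        columns=["location", "trait", "sigma_g2", "sigma_i2", "sigma_e2", "h2",
                 "phenotypic_variance", "n_genotypes", "n_years"],
    )
    return BLUETable(blues_df, comp_df)
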