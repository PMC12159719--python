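"""Synthetic multi-environment trial (MET) generator.

Emulates the statistical structure of a sparse cooperative nursery trial:
a few hundred genotypes scored at ~18 locations over multiple years, with
each genotype grown at only a subset of locations for a couple of years.
The forward model is

    y_{ilk} = m_l + g_{il} + s_{lk} + e_{ilk}

with location mean m_l, genetic value g_{il} = (X u_l)_i from additive
marker effects, a random year-within-location effect s_{lk}, and Gaussian
residual e_{ilk}.  Per-location marker effects mix a shared and a
location-specific component,

    u_l  propto  d_l * ( sqrt(rho) s + sqrt(1-rho) t_l ),

so `rho` sets the genetic correlation between locations (rho = 1 means no
genotype-by-environment interaction) and the discriminativeness multiplier
d_l sets how strongly location l separates genotypes.  The residual
variance at each location is back-solved from a target broad-sense
heritability H^2 = sg2 / (sg2 + si2 + se2), so Table-1-style heritability
profiles can be imposed directly.

Everything is deterministic under a fixed seed; the full ground truth
(effects, year effects, residuals) is returned so downstream estimators can
be tested by parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MarkerMatrix, validate_phenotypes

_RESIDUAL_FLOOR = 1e-8


class GenerationError(RuntimeError):
    """Raised when a valid dataset cannot be drawn under the config."""


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic MET generator.

    Defaults emulate the dry-bean nursery scale: ~300 genotypes, ~1,100
    retained SNPs, 18 locations, each genotype grown at ~6 locations for 2
    consecutive years, and per-location heritabilities spanning a wide
    range.
    """

    n_genotypes: int = 300
    n_markers: int = 1100
    n_locations: int = 18
    n_years: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_locations_per_genotype: int = 6
    years_per_genotype_location: int = 2
    h2_by_location: dict[str, float] | None = None
    discriminativeness_by_location: dict[str, float] | None = None
    env_correlation: float = 0.5
    year_effect_sd: float = 0.2
    location_mean_sd: float = 1.0
    genetic_sd: float = 1.0
    trait: str = "SY"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_markers", "n_locations", "n_years",
                     "mean_locations_per_genotype", "years_per_genotype_location"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.env_correlation <= 1.0:
            raise ValueError("env_correlation must be in [0, 1]")
        if self.mean_locations_per_genotype > self.n_locations:
            raise ValueError("mean_locations_per_genotype exceeds n_locations")
        if self.years_per_genotype_location > self.n_years:
            raise ValueError("years_per_genotype_location exceeds n_years")
        if self.year_effect_sd < 0 or self.location_mean_sd < 0 or self.genetic_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.h2_by_location is not None:
            names = sorted(self.h2_by_location)
        elif self.discriminativeness_by_location is not None:
            names = sorted(self.discriminativeness_by_location)
        else:
            names = [f"L{i + 1:02d}" for i in range(self.n_locations)]
        if len(names) != self.n_locations:
            raise ValueError(
                f"{len(names)} named locations but n_locations = {self.n_locations}"
            )
        if self.h2_by_location is None:
            h2 = np.linspace(0.05, 0.95, self.n_locations)
            self.h2_by_location = dict(zip(names, h2))
        if self.discriminativeness_by_location is None:
            self.discriminativeness_by_location = {l: 1.0 for l in names}
        if sorted(self.discriminativeness_by_location) != names:
            raise ValueError("h2 and discriminativeness maps name different locations")
        for l, h in self.h2_by_location.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"h2 for {l} not in [0, 1]")
        for l, d in self.discriminativeness_by_location.items():
            if d < 0:
                raise ValueError(f"discriminativeness for {l} negative")

    def location_names(self) -> list[str]:
        return sorted(self.h2_by_location)


@dataclass
class GroundTruth:
    """Truth channel of one generated dataset (stored exactly as drawn)."""

    genotype_ids: list[str]
    locations: list[str]
    shared_effects: np.ndarray            # (n_markers,) unscaled shared component
    location_effects: np.ndarray          # (n_locations, n_markers) total u_l
    location_means: np.ndarray            # (n_locations,)
    year_effects: np.ndarray              # (n_locations, n_years)
    true_genetic_values: np.ndarray       # (n_genotypes, n_locations) = X @ u_l
    residuals: np.ndarray = field(default=None)  # aligned with the phenotype table
    residual_sd_by_location: dict[str, float] = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def generate_genotypes(
    n_genotypes: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> MarkerMatrix:
    """Draw unlinked Hardy-Weinberg dosages (copies of the major allele).

    Each marker's minor allele frequency is sampled uniformly on
    ``maf_range``; columns whose realized MAF falls below
    ``min(maf_range)/2`` (including monomorphic columns) are resampled, up
    to 100 attempts per column.
    """
    if n_genotypes < 1 or n_markers < 1:
        raise ValueError("counts must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed, 0)
    dosages = np.empty((n_genotypes, n_markers), dtype=np.int64)
    floor = lo / 2.0
    for j in range(n_markers):
        for attempt in range(100):
            maf = rng.uniform(lo, hi)
            col = rng.binomial(2, 1.0 - maf, size=n_genotypes)
            f = col.sum() / (2.0 * n_genotypes)
            if min(f, 1.0 - f) >= floor:
                dosages[:, j] = col
                break
        else:
            raise GenerationError(
                f"marker column {j} stayed near-monomorphic after 100 resamples"
            )
    width = len(str(n_markers))
    snp_ids = [f"snp{j + 1:0{width}d}" for j in range(n_markers)]
    gwidth = len(str(n_genotypes))
    genotype_ids = [f"g{i + 1:0{gwidth}d}" for i in range(n_genotypes)]
    return MarkerMatrix(genotype_ids, snp_ids, dosages)


def make_design(config: SyntheticConfig) -> pd.DataFrame:
    """Sparse (genotype, location, year) incidence.

    Each genotype is assigned a uniform random subset of
    ``mean_locations_per_genotype`` locations; each assignment spans
    ``years_per_genotype_location`` consecutive years starting at a random
    year.  Redraws the whole design (up to 100 times) until every location
    retains at least two genotypes.
    """
    locations = config.location_names()
    gwidth = len(str(config.n_genotypes))
    genotype_ids = [f"g{i + 1:0{gwidth}d}" for i in range(config.n_genotypes)]
    rng = _rng(config.seed, 1)
    span = config.years_per_genotype_location
    for attempt in range(100):
        rows = []
        counts = {l: set() for l in locations}
        for g in genotype_ids:
            locs = rng.choice(
                len(locations), size=config.mean_locations_per_genotype, replace=False
            )
            for li in locs:
                loc = locations[li]
                start = rng.integers(0, config.n_years - span + 1)
                counts[loc].add(g)
                for y in range(start, start + span):
                    rows.append((g, loc, int(y)))
        if all(len(v) >= 2 for v in counts.values()):
            return pd.DataFrame(rows, columns=["genotype_id", "location", "year"])
    raise GenerationError("a location retained < 2 genotypes after 100 design redraws")


def _residual_sd(sigma_g2: float, h2: float, sigma_y2: float) -> float:
    """Back-solve residual variance from H2 = sg2/(sg2 + sy2 + se2)."""
    if h2 <= 0.0:
        if sigma_g2 > 0:
            raise GenerationError(
                "target H2 = 0 with nonzero genetic variance implies infinite "
                "residual variance"
            )
        return 1.0
    if h2 >= 1.0:
        if sigma_y2 > 0:
            raise GenerationError(
                "target H2 = 1 requires zero year-effect variance"
            )
        return 0.0
    se2 = sigma_g2 * (1.0 - h2) / h2 - sigma_y2
    if se2 < _RESIDUAL_FLOOR:
        warnings.warn(
            f"residual variance back-solve hit the floor ({se2:.3g} < "
            f"{_RESIDUAL_FLOOR}); realized heritability will fall short of target",
            stacklevel=2,
        )
        se2 = _RESIDUAL_FLOOR
    return float(np.sqrt(se2))


def generate_met(
    config: SyntheticConfig, genotypes: MarkerMatrix
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate phenotypes for the sparse design; return table + truth."""
    if genotypes.n_genotypes != config.n_genotypes:
        raise ValueError("marker matrix inconsistent with config (n_genotypes)")
    if genotypes.n_snps != config.n_markers:
        raise ValueError("marker matrix inconsistent with config (n_markers)")
    locations = config.location_names()
    L, M = len(locations), config.n_markers
    rng = _rng(config.seed, 2)
    rho = config.env_correlation

    shared = rng.standard_normal(M)
    specific = rng.standard_normal((L, M))
    X = genotypes.dosages.astype(float)

    location_effects = np.empty((L, M))
    genetic = np.empty((config.n_genotypes, L))
    for j, loc in enumerate(locations):
        base = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * specific[j]
        g_raw = X @ base
        sd_raw = float(np.std(g_raw, ddof=1)) if config.n_genotypes > 1 else 0.0
        d = config.discriminativeness_by_location[loc]
        alpha = 0.0 if sd_raw == 0.0 else d * config.genetic_sd / sd_raw
        location_effects[j] = alpha * base
        genetic[:, j] = alpha * g_raw

    location_means = rng.normal(0.0, config.location_mean_sd, size=L)
    year_effects = rng.normal(0.0, config.year_effect_sd, size=(L, config.n_years))

    design = make_design(config)
    gidx = {g: i for i, g in enumerate(genotypes.genotype_ids)}
    lidx = {l: j for j, l in enumerate(locations)}

    # residual sd per location, from realized genetic variance among the
    # genotypes actually grown there
    sigma_y2 = config.year_effect_sd ** 2
    resid_sd = {}
    for loc in locations:
        grown = design.loc[design["location"] == loc, "genotype_id"].unique()
        gvals = genetic[[gidx[g] for g in grown], lidx[loc]]
        sg2 = float(np.var(gvals, ddof=1)) if len(gvals) > 1 else 0.0
        resid_sd[loc] = _residual_sd(sg2, config.h2_by_location[loc], sigma_y2)

    gi = design["genotype_id"].map(gidx).to_numpy()
    lj = design["location"].map(lidx).to_numpy()
    yk = design["year"].to_numpy()
    sd_vec = design["location"].map(resid_sd).to_numpy(dtype=float)
    residuals = rng.standard_normal(len(design)) * sd_vec
    values = (
        location_means[lj]
        + genetic[gi, lj]
        + year_effects[lj, yk]
        + residuals
    )
    phen = design.assign(trait=config.trait, value=values)
    phen = validate_phenotypes(phen)

    truth = GroundTruth(
        genotype_ids=list(genotypes.genotype_ids),
        locations=locations,
        shared_effects=shared,
        location_effects=location_effects,
        location_means=location_means,
        year_effects=year_effects,
        true_genetic_values=genetic,
        residuals=residuals,
        residual_sd_by_location=resid_sd,
    )
    return phen, truth


def h2_profile_constant_noise(
    disc_by_location: dict[str, float],
    genetic_sd: float = 1.0,
    year_effect_sd: float = 0.2,
    residual_sd: float = 1.0,
) -> dict[str, float]:
    """Heritability profile implied by constant absolute noise.

    Field trials with a wide per-location H2 range for the same trait are
    usually noise-driven: measurement/plot error is roughly constant in
    trait units while genotypic variance differs by location.  Under the
    generator's scaling (sg at location l = d_l * genetic_sd) that gives

        H2_l = (d_l g)^2 / ((d_l g)^2 + sy^2 + se^2).
    """
    sy2, se2 = year_effect_sd ** 2, residual_sd ** 2
    out = {}
    for loc, d in disc_by_location.items():
        sg2 = (d * genetic_sd) ** 2
        out[loc] = sg2 / (sg2 + sy2 + se2)
    return out


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[MarkerMatrix, pd.DataFrame, GroundTruth]:
    """Convenience: genotypes + phenotypes + truth from one config."""
    markers = generate_genotypes(
        config.n_genotypes, config.n_markers, config.maf_range, config.seed
    )
    phen, truth = generate_met(config, markers)
    return markers, phen, truth
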