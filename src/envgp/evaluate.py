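"""Leave-one-location-out cross-validation and summary statistics.

Each location in turn is held out as the test set; every approach x base
combination trains on the remaining locations and predicts the held-out
location's BLUEs.  Accuracy is the Pearson correlation between observed
and predicted values.  All randomness is seeded per fold from the run
seed and the test-location name, so fold order cannot change any result.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .datatypes import ModelingDataset
from .ensembles import (
    EnsembleModel,
    holdout_split,
    optimize_ensemble,
    train_bagged_ensemble,
    train_ensemble,
    train_singular,
)
from .metrics import accuracy

APPROACHES = ("singular", "ensemble", "optimized")
BASES = ("linear", "ridge", "network")


@dataclass
class NetworkSettings:
    """Desk-scale defaults for the network base inside CV.

    ``tune_draws`` is the random-search budget per fold (the full-scale
    search uses 300 draws); ``n_submodels`` is the environment-bagging
    ensemble size.
    """

    tune_draws: int = 30
    max_epochs: int = models.MAX_EPOCHS
    n_submodels: int = 5
    hyperparams: models.NetworkHyperparams | None = None


def fold_seed(seed: int, location: str) -> int:
    """Per-fold sub-seed from the run seed and test-location name only."""
    h = zlib.crc32(location.encode("utf8"))
    return (int(seed) * 2654435761 + h) % (2**31 - 1)


def _make_fitter(base: str, dataset: ModelingDataset, test_location: str,
                 fseed: int, net: NetworkSettings):
    """Base-model fitter with per-fold tuning on training-side data only."""
    if base == "linear":
        return lambda X, y, s: models.fit_ols(X, y)
    train_locs = dataset.training_locations(test_location)
    Xp, yp = dataset.stacked(train_locs)
    if base == "ridge":
        lam = models.choose_ridge_lambda(Xp, yp, seed=fseed)
        return lambda X, y, s: models.fit_ridge(X, y, lam)
    if base == "network":
        hp = net.hyperparams
        if hp is None:
            hp = models.tune_network(Xp, yp, n_draws=net.tune_draws, seed=fseed,
                                     max_epochs=net.max_epochs)
        return lambda X, y, s: models.fit_network(X, y, hp, seed=s,
                                                  max_epochs=net.max_epochs)
    raise ValueError(f"unknown base {base!r}")


def _refit_membership(membership: list[list[str]], dataset: ModelingDataset,
                      fitter, fseed: int, approach: str,
                      decisions) -> EnsembleModel:
    """Re-train surviving submodels on their full (un-held-out) blocks."""
    submodels = []
    for i, bag in enumerate(membership):
        X, y = dataset.stacked(bag)
        submodels.append(fitter(X, y, (fseed * 31 + i) % (2**31 - 1)))
    return EnsembleModel(submodels, [list(b) for b in membership],
                         approach=approach, decisions=decisions)


def _train_full_ensemble(dataset, base, fitter, test_location, fseed, net):
    if base == "network":
        return train_bagged_ensemble(dataset, fitter, net.n_submodels, fseed,
                                     test_location)
    return train_ensemble(dataset, fitter, test_location, fseed)


def loo_location_cv(
    dataset: ModelingDataset,
    approaches: tuple[str, ...] = APPROACHES,
    bases: tuple[str, ...] = ("linear", "ridge"),
    seed: int = 0,
    validation_mode: str = "holdout",
    network: NetworkSettings | None = None,
    components: pd.DataFrame | None = None,
    run_log: list | None = None,
) -> pd.DataFrame:
    """Leave-one-location-out CV over approaches x bases.

    Returns one row per (trait, test_location, approach, base) with the
    Pearson accuracy, test size, the test location's phenotypic variance
    (sample variance of its BLUEs) and, when a components table is given,
    its broad-sense heritability.  ``validation_mode`` is "holdout"
    (default; optimization scored on a training-side genotype holdout) or
    "leaky" (scored on the test location itself).
    """
    for a in approaches:
        if a not in APPROACHES:
            raise ValueError(f"unknown approach {a!r}")
    for b in bases:
        if b not in BASES:
            raise ValueError(f"unknown base {b!r}")
    if validation_mode not in ("holdout", "leaky"):
        raise ValueError(f"unknown validation mode {validation_mode!r}")
    locations = dataset.locations
    if len(locations) < 2:
        raise ValueError("leave-one-location-out needs >= 2 locations")

    h2_by_loc: dict[str, float] = {}
    if components is not None:
        sub = components[components["trait"] == dataset.trait]
        h2_by_loc = dict(zip(sub["location"], sub["h2"]))

    rows = []
    for loc in locations:
        fseed = fold_seed(seed, loc)
        test = dataset.blocks[loc]
        pvar = float(np.var(test.y, ddof=1)) if len(test.y) > 1 else float("nan")
        if run_log is not None:
            run_log.append({"event": "fold", "test_location": loc, "seed": fseed})
        for base in bases:
            fitter = _make_fitter(base, dataset, loc, fseed, network
                                  or NetworkSettings())
            net = network or NetworkSettings()
            cache: dict[str, EnsembleModel] = {}
            for approach in approaches:
                try:
                    model = _train_approach(
                        approach, dataset, base, fitter, loc, fseed, net,
                        validation_mode, cache, run_log,
                    )
                    acc = accuracy(test.y, model.predict(test.X))
                except (ValueError, models.DivergenceError) as exc:
                    warnings.warn(
                        f"fold {loc!r} {approach}/{base}: accuracy undefined "
                        f"({exc}); row flagged",
                        stacklevel=2,
                    )
                    acc = float("nan")
                rows.append({
                    "trait": dataset.trait, "test_location": loc,
                    "approach": approach, "base": base, "accuracy": acc,
                    "n_test": len(test.y), "phenotypic_variance": pvar,
                    "h2": h2_by_loc.get(loc, float("nan")),
                })
    return pd.DataFrame(rows)


def _train_approach(approach, dataset, base, fitter, loc, fseed, net,
                    validation_mode, cache, run_log):
    if approach == "singular":
        return train_singular(dataset, fitter, loc, fseed)
    if "ensemble" not in cache:
        cache["ensemble"] = _train_full_ensemble(dataset, base, fitter, loc,
                                                 fseed, net)
    if approach == "ensemble":
        return cache["ensemble"]
    # optimized
    if validation_mode == "leaky":
        test = dataset.blocks[loc]
        optimized = optimize_ensemble(cache["ensemble"], test.X, test.y)
    else:
        reduced, Xv, yv = holdout_split(dataset, loc, seed=fseed)
        full_reduced = _train_full_ensemble(reduced, base, fitter, loc, fseed, net)
        screened = optimize_ensemble(full_reduced, Xv, yv)
        optimized = _refit_membership(screened.membership, dataset, fitter,
                                      fseed, "optimized", screened.decisions)
    if run_log is not None:
        for d in optimized.decisions:
            run_log.append({
                "event": "optimization", "test_location": loc, "base": base,
                "membership": d.membership, "baseline": d.baseline_accuracy,
                "dropout": d.dropout_accuracy, "excluded": d.excluded,
                "validation_mode": validation_mode,
            })
    return optimized


def variance_threshold_stat(
    results: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Phenotypic-variance threshold below which the ensemble wins.

    Per trait x base: locations are sorted by phenotypic variance
    ascending; the threshold v* is the largest variance such that the
    ensemble beats the singular model at every location with variance
    <= v* (0 if the ensemble loses at the lowest-variance location).  The
    proportion is v* / max(variance) x 100; the overall statistic is the
    mean proportion over trait x base combinations with a defined
    threshold.
    """
    needed = {"singular", "ensemble"}
    if not needed <= set(results["approach"]):
        raise ValueError("results must contain singular and ensemble rows")
    combos = []
    for (trait, base), grp in results.groupby(["trait", "base"]):
        piv = grp.pivot_table(index="test_location", columns="approach",
                              values="accuracy", aggfunc="first")
        if not needed <= set(piv.columns):
            continue
        pv = grp.groupby("test_location")["phenotypic_variance"].first()
        tbl = piv.join(pv).dropna(subset=["singular", "ensemble",
                                          "phenotypic_variance"])
        if tbl.empty:
            continue
        tbl = tbl.sort_values("phenotypic_variance", kind="stable")
        wins = (tbl["ensemble"] > tbl["singular"]).to_numpy()
        k = 0
        while k < len(wins) and wins[k]:
            k += 1
        vmax = float(tbl["phenotypic_variance"].max())
        vstar = float(tbl["phenotypic_variance"].iloc[k - 1]) if k > 0 else 0.0
        proportion = 100.0 * vstar / vmax if vmax > 0 else float("nan")
        if np.isfinite(proportion):
            combos.append({"trait": trait, "base": base,
                           "threshold_variance": vstar, "max_variance": vmax,
                           "proportion_pct": proportion})
    if not combos:
        raise ValueError("no trait x base combination has a defined threshold")
    combo_df = pd.DataFrame(combos)
    return combo_df, float(combo_df["proportion_pct"].mean())
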