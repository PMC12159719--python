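"""Training regimes over environments: singular, ensemble, optimized, bagged.

* singular — one base model on the row-concatenation of all training
  locations.
* ensemble — one submodel per training location; the ensemble prediction
  is the arithmetic mean of submodel predictions (equal weights, always).
* bagged — for networks: each submodel trains on L location blocks drawn
  with replacement from the L training locations (environment bagging).
* optimized — greedy single-dropout screening: starting from the full
  ensemble's validation accuracy, each submodel is left out one by one
  (judged against the full ensemble, not sequentially); a submodel is
  excluded iff dropping it strictly raises validation accuracy.

The validation set for optimization is, by default, a genotype-stratified
20% holdout carved from the training locations' rows (no test-location
data touches any training decision).  A "leaky" mode that scores
dropouts on the test location itself is provided for protocol replication
and labeled as leaky in every manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .datatypes import LocationBlock, ModelingDataset
from .metrics import accuracy

Fitter = Callable[[np.ndarray, np.ndarray, int], object]


@dataclass
class OptimizationDecision:
    """Audit record of one single-dropout evaluation."""

    submodel: int
    membership: list[str]
    baseline_accuracy: float
    dropout_accuracy: float
    excluded: bool


@dataclass
class EnsembleModel:
    """Ordered submodels with per-submodel training-location membership."""

    submodels: list
    membership: list[list[str]]
    approach: str  # singular | ensemble | optimized | bagged
    decisions: list[OptimizationDecision] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.submodels:
            raise ValueError("an ensemble needs at least one submodel")
        if len(self.submodels) != len(self.membership):
            raise ValueError("membership must align with submodels")

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.submodels])
        return preds.mean(axis=0)


def ensemble_predict(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of submodel predictions (equal weights)."""
    return model.predict(X)


def train_singular(
    dataset: ModelingDataset, fitter: Fitter, test_location: str, seed: int = 0
) -> EnsembleModel:
    """One base model on all non-test locations pooled."""
    train_locs = dataset.training_locations(test_location)
    if not train_locs:
        raise ValueError("no training locations besides the test location")
    X, y = dataset.stacked(train_locs)
    if X.shape[0] == 0:
        raise ValueError("no training rows")
    model = fitter(X, y, seed)
    return EnsembleModel([model], [list(train_locs)], approach="singular")


def train_ensemble(
    dataset: ModelingDataset, fitter: Fitter, test_location: str, seed: int = 0
) -> EnsembleModel:
    """One submodel per training location (>= 2 rows each)."""
    train_locs = dataset.training_locations(test_location)
    submodels, membership = [], []
    for i, loc in enumerate(train_locs):
        block = dataset.blocks[loc]
        if block.X.shape[0] < 2:
            warnings.warn(f"location {loc!r} has < 2 rows; no submodel trained",
                          stacklevel=2)
            continue
        submodels.append(fitter(block.X, block.y, _sub_seed(seed, i)))
        membership.append([loc])
    if not submodels:
        raise ValueError("every training location was too small for a submodel")
    return EnsembleModel(submodels, membership, approach="ensemble")


def train_bagged_ensemble(
    dataset: ModelingDataset,
    fitter: Fitter,
    n_submodels: int,
    seed: int,
    test_location: str,
) -> EnsembleModel:
    """Environment bagging: each bag is L locations drawn with replacement."""
    if n_submodels < 1:
        raise ValueError("n_submodels must be >= 1")
    train_locs = dataset.training_locations(test_location)
    if not train_locs:
        raise ValueError("no training locations besides the test location")
    rng = np.random.default_rng([int(seed), 13])
    L = len(train_locs)
    submodels, membership = [], []
    for i in range(n_submodels):
        bag = [train_locs[j] for j in rng.integers(0, L, size=L)]
        X, y = dataset.stacked(bag)
        submodels.append(fitter(X, y, _sub_seed(seed, i)))
        membership.append(bag)
    return EnsembleModel(submodels, membership, approach="bagged")


def optimize_ensemble(
    full: EnsembleModel, validation_X: np.ndarray, validation_y: np.ndarray
) -> EnsembleModel:
    """Greedy single-dropout screening against the full-ensemble baseline.

    Each submodel's dropout is judged against the FULL ensemble; it is
    excluded iff accuracy without it strictly exceeds the baseline.  If
    every submodel would be excluded, the one whose dropout hurt most (the
    most valuable) is retained with a warning.  Fitted submodels are never
    re-trained here.
    """
    if len(full.submodels) < 2:
        raise ValueError("optimization needs >= 2 submodels")
    validation_y = np.asarray(validation_y, dtype=float)
    if validation_y.size == 0:
        raise ValueError("validation set is empty")
    preds = np.stack([m.predict(validation_X) for m in full.submodels])
    baseline = accuracy(validation_y, preds.mean(axis=0))
    if not np.isfinite(baseline):
        raise ValueError(
            "validation correlation undefined (constant predictions or truth); "
            "enlarge the validation split"
        )
    n = len(full.submodels)
    decisions, keep = [], []
    dropout_accs = np.empty(n)
    total = preds.sum(axis=0)
    for i in range(n):
        without = (total - preds[i]) / (n - 1)
        acc = accuracy(validation_y, without)
        dropout_accs[i] = acc if np.isfinite(acc) else -np.inf
        excluded = np.isfinite(acc) and acc > baseline
        decisions.append(OptimizationDecision(
            submodel=i, membership=list(full.membership[i]),
            baseline_accuracy=float(baseline), dropout_accuracy=float(acc),
            excluded=bool(excluded),
        ))
        if not excluded:
            keep.append(i)
    if not keep:
        best = int(np.argmin(dropout_accs))
        warnings.warn(
            "every submodel's dropout raised validation accuracy; retaining the "
            "single most valuable submodel",
            stacklevel=2,
        )
        keep = [best]
    return EnsembleModel(
        [full.submodels[i] for i in keep],
        [list(full.membership[i]) for i in keep],
        approach="optimized",
        decisions=decisions,
    )


def holdout_split(
    dataset: ModelingDataset,
    test_location: str,
    fraction: float = 0.2,
    seed: int = 0,
) -> tuple[ModelingDataset, np.ndarray, np.ndarray]:
    """Genotype-stratified validation holdout from the training locations.

    A random ``fraction`` of the training genotypes is held out; all of
    their rows (across every training location) form the validation set,
    so no genotype straddles the split.  Returns the reduced dataset plus
    the validation features/responses.
    """
    train_locs = dataset.training_locations(test_location)
    all_genotypes = sorted({g for l in train_locs
                            for g in dataset.blocks[l].genotype_ids})
    rng = np.random.default_rng([int(seed), 17])
    n_hold = max(2, int(round(fraction * len(all_genotypes))))
    held = set(rng.choice(all_genotypes, size=min(n_hold, len(all_genotypes) - 2),
                          replace=False))
    reduced_blocks, val_X, val_y = {}, [], []
    for loc in dataset.locations:
        block = dataset.blocks[loc]
        if loc == test_location:
            reduced_blocks[loc] = block
            continue
        mask = np.array([g not in held for g in block.genotype_ids])
        if mask.sum() >= 2:
            reduced_blocks[loc] = LocationBlock(
                [g for g, m in zip(block.genotype_ids, mask) if m],
                block.X[mask], block.y[mask],
            )
        if (~mask).any():
            val_X.append(block.X[~mask])
            val_y.append(block.y[~mask])
    if not val_X:
        raise ValueError("holdout produced an empty validation set")
    reduced = ModelingDataset(dataset.trait, dataset.selected_snp_ids, reduced_blocks)
    return reduced, np.vstack(val_X), np.concatenate(val_y)


def _sub_seed(seed: int, i: int) -> int:
    return (int(seed) * 1009 + i + 1) % (2**31 - 1)
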