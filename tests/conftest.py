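"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pytest

from envgp.datatypes import LocationBlock, ModelingDataset
from envgp.metrics import accuracy

# statsmodels REML emits benign convergence chatter on tiny fixtures
warnings.filterwarnings("ignore", module="statsmodels")


class FixedPredictor:
    """Stub base model returning pre-set predictions (oracle plumbing)."""

    def __init__(self, preds):
        self.preds = np.asarray(preds, dtype=float)

    def predict(self, X):
        return self.preds


def brute_force_pca_select(X, snp_ids, n_components):
    """Independent PCA-selection oracle: explicit covariance, full eigen
    decomposition, greedy per-component argmax |loading| with dedup and
    lexicographic tie-break."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / max(X.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(-evals, kind="stable")
    selected, taken = [], set()
    for comp in order[:n_components]:
        v = np.round(np.abs(evecs[:, comp]), 10)
        rank = sorted(range(len(snp_ids)), key=lambda j: (-v[j], snp_ids[j]))
        for j in rank:
            if snp_ids[j] not in taken:
                selected.append(snp_ids[j])
                taken.add(snp_ids[j])
                break
    return selected


def brute_force_best_subset(preds, y):
    """Exhaustive best-accuracy submodel subset (oracle for the greedy
    single-dropout optimizer)."""
    n = len(preds)
    best, best_acc = None, -np.inf
    for r in range(1, n + 1):
        for sub in combinations(range(n), r):
            acc = accuracy(y, np.mean([preds[i] for i in sub], axis=0))
            if np.isfinite(acc) and acc > best_acc + 1e-12:
                best_acc, best = acc, set(sub)
    return best, best_acc


def make_linear_dataset(
    n_locations=4, n_per_block=30, n_features=5, noise=0.3, seed=0,
    identical_blocks=False,
):
    """Small ModelingDataset with a common linear signal per location."""
    rng = np.random.default_rng(seed)
    beta = rng.normal(size=n_features)
    blocks = {}
    X0 = rng.normal(size=(n_per_block, n_features))
    y0 = X0 @ beta + noise * rng.normal(size=n_per_block)
    for j in range(n_locations):
        if identical_blocks:
            X, y = X0, y0
            gids = [f"g{i}" for i in range(n_per_block)]
        else:
            X = rng.normal(size=(n_per_block, n_features))
            y = X @ beta + noise * rng.normal(size=n_per_block)
            gids = [f"g{j}_{i}" for i in range(n_per_block)]
        blocks[f"L{j + 1:02d}"] = LocationBlock(gids, X, y)
    return ModelingDataset(trait="T", selected_snp_ids=[f"s{k}" for k in
                                                        range(n_features)],
                           blocks=blocks)


@pytest.fixture
def linear_dataset():
    return make_linear_dataset()
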