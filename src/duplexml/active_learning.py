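"""Query-by-committee active learning over an unlabeled pool.

A committee of models trained with different weight initializations
scores every unlabeled pool item; the disagreement statistic is the
maximal absolute deviation of any member's prediction from the committee
mean::

    ε_i = max_m | G_{m,i} − ⟨G_{·,i}⟩ |

Items with ε above a threshold are *candidates*; the largest-ε
candidates (up to a per-iteration cap) are labeled by the oracle, added
to the training set, and the committee is retrained from scratch.  The
loop terminates when no candidate remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regressor import ConvNetRegressor

__all__ = [
    "ALConfig",
    "ALResult",
    "ALWarning",
    "DESK_COMMITTEE_CONFIG",
    "epsilon",
    "select_candidates",
    "committee_factory",
    "run_loop",
]


class ALWarning(UserWarning):
    """Non-fatal active-learning diagnostics (e.g. iteration cap hit)."""


@dataclass
class ALConfig:
    """Acquisition-loop settings.

    Defaults follow the hybridization campaign (ε threshold 0.6, up to 16
    acquisitions per iteration, committee of 4, 64 initial labels); the
    displacement campaign uses threshold 0.5 and cap 10.
    """

    committee_size: int = 4
    threshold: float = 0.6
    max_per_iteration: int = 16
    initial_size: int = 64
    max_iterations: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.committee_size < 2:
            raise ValueError("committee size must be >= 2")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class ALResult:
    labeled_indices: list
    labels: dict  # pool index -> label
    log: pd.DataFrame  # iteration, n_labeled, n_candidates, mean_train_rmse
    committee: list = field(default_factory=list)
    converged: bool = True


def epsilon(predictions) -> np.ndarray:
    """Per-sample maximal absolute deviation from the committee mean.

    ``predictions`` has shape (committee, n_samples).
    """
    P = np.asarray(predictions, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError(f"need a (committee >= 2, samples) array, got {P.shape}")
    return np.abs(P - P.mean(axis=0, keepdims=True)).max(axis=0)


def select_candidates(eps, threshold: float, cap: int) -> np.ndarray:
    """Indices with ε > threshold, sorted ε-descending (ties by index),
    truncated to ``cap``."""
    eps = np.asarray(eps, dtype=float)
    above = np.flatnonzero(eps > threshold)
    order = above[np.lexsort((above, -eps[above]))]
    return order[:cap]


#: Desk-scale committee configuration: a compact network and optimizer
#: sized for pools of ~500 items on one CPU.  Full-scale defaults
#: (32 filters, 256/128 hidden, batch 999, lr 0.001) remain the
#: :class:`~duplexml.regressor.ConvNetRegressor` defaults.
DESK_COMMITTEE_CONFIG = {
    "n_filters": 32,
    "hidden_sizes": (128, 64),
    "batch_size": 32,
    "learning_rate": 0.003,
    "max_epochs": 300,
    "patience": 35,
    "dropout": 0.1,
}


def committee_factory(**overrides):
    """A factory mapping a seed to a fresh :class:`ConvNetRegressor`."""

    def factory(seed: int) -> ConvNetRegressor:
        return ConvNetRegressor(random_state=seed, **overrides)

    return factory


def _member_seed(base: int, iteration: int, member: int) -> int:
    return int((base * 1_000_003 + iteration * 9176 + member * 131 + 17) % (2**31))


def run_loop(
    X_pool: np.ndarray,
    oracle,
    config: ALConfig,
    model_factory=None,
    initial_indices=None,
) -> ALResult:
    """Run the acquisition loop until zero candidates remain.

    ``X_pool`` holds the featurized pool; ``oracle(index)`` returns the
    label of one pool item.  Each iteration trains ``committee_size``
    models from scratch with distinct initialization seeds on the current
    labeled set, scores the unlabeled remainder, and acquires the top
    candidates.  A hard iteration cap guards against non-termination and
    emits an :class:`ALWarning`.
    """
    X_pool = np.asarray(X_pool, dtype=float)
    n_pool = X_pool.shape[0]
    if n_pool == 0:
        raise ValueError("empty pool")
    model_factory = model_factory or committee_factory()
    rng = np.random.default_rng(config.seed)

    if initial_indices is None:
        initial_indices = rng.choice(n_pool, size=config.initial_size, replace=False)
    labeled = list(int(i) for i in initial_indices)
    labels = {i: float(oracle(i)) for i in labeled}

    rows = []
    committee: list = []
    converged = False
    for iteration in range(config.max_iterations):
        X_lab = X_pool[labeled]
        y_lab = np.array([labels[i] for i in labeled])
        committee = []
        train_rmses = []
        for m in range(config.committee_size):
            model = model_factory(_member_seed(config.seed, iteration, m))
            model.fit(X_lab, y_lab)
            committee.append(model)
            resid = model.predict(X_lab) - y_lab
            train_rmses.append(float(np.sqrt(np.mean(resid**2))))

        unlabeled = np.array([i for i in range(n_pool) if i not in labels], dtype=int)
        if unlabeled.size:
            preds = np.stack([m.predict(X_pool[unlabeled]) for m in committee])
            eps = epsilon(preds)
            chosen_local = select_candidates(eps, config.threshold, config.max_per_iteration)
            n_candidates = int(np.sum(eps > config.threshold))
            chosen = unlabeled[chosen_local]
        else:
            n_candidates = 0
            chosen = np.array([], dtype=int)

        rows.append(
            {
                "iteration": iteration,
                "n_labeled": len(labeled),
                "n_candidates": n_candidates,
                "mean_train_rmse": float(np.mean(train_rmses)),
            }
        )
        if n_candidates == 0:
            converged = True
            break
        for i in chosen:
            i = int(i)
            labels[i] = float(oracle(i))
            labeled.append(i)

    if not converged:
        warnings.warn(
            f"active learning hit the iteration cap ({config.max_iterations}) "
            "with candidates remaining",
            ALWarning,
        )
    return ALResult(
        labeled_indices=labeled,
        labels=labels,
        log=pd.DataFrame(rows),
        committee=committee,
        converged=converged,
    )
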