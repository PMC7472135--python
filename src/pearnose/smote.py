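"""SMOTE oversampling and majority-count class balancing.

SMOTE creates synthetic minority-class rows on the segment between a
minority row ``x_m`` and one of its k nearest minority neighbours ``x_n``:
``x_i = x_m + alpha * (x_n - x_m)`` with ``alpha ~ U(0, 1)``.  An
alternative ``mode="paper-sign"`` flips the direction of the step,
``x_i = x_m + alpha * (x_m - x_n)``, i.e. extrapolates away from the
neighbour; it is provided because some descriptions of the method print
the difference that way round, but interpolation is the default.

:func:`balance_dataset` raises every minority grade to the majority-grade
row count.  Applied to the study cohorts' stable-value tables it turns the
14,400-row training matrix into 27,720 rows (6 x 4,620) and the 6,120-row
test matrix into 13,680 rows (6 x 2,280).  Balancing a *test* table is
methodologically unusual - it changes what the evaluation measures - so
both the balanced and the original evaluation paths are kept downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .data import N_CLASSES, FeatureTable
from .errors import SamplingError

_MODES = ("standard", "paper-sign")


@dataclass
class BalancePlan:
    """Bookkeeping of one balancing run: per-grade original / added / new
    row counts plus the knobs that produced them."""

    classes: np.ndarray
    original: np.ndarray
    added: np.ndarray
    target: int
    k_neighbors: int
    seed: int
    mode: str = "standard"

    def __post_init__(self) -> None:
        if int(self.original.max(initial=0)) != self.target:
            raise SamplingError("balance target must equal the majority count")
        if np.any(self.added != self.target - self.original):
            raise SamplingError("added counts must be target - original")

    @property
    def new(self) -> np.ndarray:
        return self.original + self.added

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.classes,
                "original_rows": self.original,
                "added_rows": self.added,
                "new_rows": self.new,
            }
        )


def smote_generate(
    X_minority: np.ndarray,
    n_new: int,
    k: int = 5,
    rng: np.random.Generator | None = None,
    mode: str = "standard",
) -> np.ndarray:
    """Draw ``n_new`` synthetic rows from one minority class.

    Base rows are drawn uniformly with the supplied generator; for each
    base, one of its k nearest (Euclidean) minority neighbours is drawn
    uniformly and a step of length ``alpha ~ U(0,1)`` is taken along the
    segment (or away from it in ``paper-sign`` mode).
    """
    X = np.asarray(X_minority, dtype=float)
    if X.ndim != 2:
        raise SamplingError("X_minority must be 2-D")
    m = len(X)
    if n_new < 0:
        raise SamplingError("n_new must be >= 0")
    if m < 2:
        raise SamplingError(
            f"cannot interpolate within a class of {m} row(s); need >= 2"
        )
    if not 1 <= k <= m - 1:
        raise SamplingError(f"k={k} must satisfy 1 <= k <= n_rows-1 = {m - 1}")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if rng is None:
        rng = np.random.default_rng()
    if n_new == 0:
        return np.empty((0, X.shape[1]))

    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    # ties broken by row index; only the k-nearest set matters, not its order
    neighbors = np.argsort(d, axis=1, kind="stable")[:, :k]

    base_idx = rng.integers(0, m, size=n_new)
    nbr_choice = rng.integers(0, k, size=n_new)
    alpha = rng.uniform(0.0, 1.0, size=n_new)
    base = X[base_idx]
    nbr = X[neighbors[base_idx, nbr_choice]]
    step = (nbr - base) if mode == "standard" else (base - nbr)
    return base + alpha[:, None] * step


def balance_dataset(
    table: FeatureTable,
    k: int = 5,
    seed: int = 0,
    mode: str = "standard",
) -> tuple[FeatureTable, BalancePlan]:
    """Oversample every minority grade up to the majority-grade count.

    Original rows come first, in their input order; synthetic rows follow,
    grouped by grade, with ids ``smote-c<grade>-<i>``.  For a grade with
    2 <= M <= k rows the neighbour count is reduced to M - 1; a grade with
    fewer than 2 rows (and a deficit) cannot be interpolated and raises.
    """
    counts = table.class_counts()
    present = counts > 0
    target = int(counts.max())
    added = np.where(present, target - counts, 0)

    rng = np.random.default_rng(seed)
    new_X, new_y, new_ids = [table.X], [table.y], [table.ids]
    for label in range(N_CLASSES):
        n_add = int(added[label])
        if n_add == 0:
            continue
        rows = table.X[table.y == label]
        if len(rows) < 2:
            raise SamplingError(
                f"class {label} has {len(rows)} row(s); SMOTE needs >= 2 and "
                "no neighbour-count reduction can fix that"
            )
        k_eff = min(k, len(rows) - 1)
        synth = smote_generate(rows, n_add, k=k_eff, rng=rng, mode=mode)
        new_X.append(synth)
        new_y.append(np.full(n_add, label))
        new_ids.append(np.array(
            [f"smote-c{label}-{i:05d}" for i in range(n_add)], dtype=object
        ))
    balanced = FeatureTable(
        X=np.vstack(new_X),
        y=np.concatenate(new_y),
        ids=np.concatenate(new_ids),
    )
    plan = BalancePlan(
        classes=np.arange(N_CLASSES),
        original=counts,
        added=added,
        target=target,
        k_neighbors=k,
        seed=seed,
        mode=mode,
    )
    return balanced, plan


class SMOTEOverSampler(BaseEstimator):
    """Estimator-style wrapper around :func:`balance_dataset`.

    ``fit_resample(X, y)`` returns a balanced ``(X, y)`` pair; the plan of
    the last call is kept in ``plan_``.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0,
                 mode: str = "standard"):
        self.k_neighbors = k_neighbors
        self.random_state = random_state
        self.mode = mode

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        table = FeatureTable(X=X, y=y, ids=np.arange(len(y)).astype(object))
        balanced, plan = balance_dataset(
            table, k=self.k_neighbors, seed=self.random_state, mode=self.mode
        )
        self.plan_ = plan
        return balanced.X, balanced.y
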