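"""Validation designs for closed-set identification.

Four designs, mirroring increasingly strict uses of a multi-day cohort:

* ``run_loo`` — leave-one-out over all samples of the table (e.g. the 36
  samples of one region on one day), deterministic.
* ``run_repeated_one_out_per_participant`` — each iteration randomly assigns
  every participant's ``m`` samples to ``m`` folds; each fold trains on
  ``m - 1`` samples per participant and tests on the held-out one, so every
  sample is tested exactly once per iteration.  Repeated (default 500
  iterations) to yield an accuracy distribution whose mean is the "true
  accuracy" of the model.
* ``run_accumulated_days`` — the same scheme on growing day windows; with
  ``r`` replicates/day and ``k`` days there are ``r * k`` folds, keeping the
  train-(rk-1)/test-1-per-person stringency constant as data accumulate.
* ``run_across_day_holdout`` — fit on whole days, test on a fully unseen
  day; the strictest design and the only one that probes cross-day drift.

Folds always partition the evaluation set, and accuracy is the fraction of
held-out samples whose predicted participant matches the truth
(micro-averaged; classes are balanced by design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .classify import ModelConfig, fit, predict
from .datamodel import EndpointTable, ValidationError
from .preprocess import subset

SCHEME_KINDS = ("loo", "one_sample_per_participant_out", "day_holdout")


@dataclass(frozen=True)
class FoldScheme:
    """Declarative description of a validation design."""

    kind: str = "one_sample_per_participant_out"
    n_iterations: int = 500
    seed: int = 0
    train_days: tuple[int, ...] = ()
    test_day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"kind must be one of {SCHEME_KINDS}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class AccuracyDistribution:
    """Accuracies over repeated iterations, with summaries.

    ``mean`` is reported as the model's true accuracy; ``median`` is the
    summary compared against permutation nulls.
    """

    accuracies: np.ndarray
    scheme: FoldScheme

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.accuracies.ndim != 1 or len(self.accuracies) == 0:
            raise ValueError("accuracies must be a non-empty 1-D sequence")
        if ((self.accuracies < 0) | (self.accuracies > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def median(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def _xy(table: EndpointTable, labels: Optional[np.ndarray] = None):
    frame = table.frame
    if (frame["kind"] != "body").any():
        raise ValidationError("validation expects a body-only table (run preprocessing first)")
    x = table.matrix()
    y = labels if labels is not None else table.labels()
    return x, np.asarray(y, dtype=object)


def run_loo(table: EndpointTable, model_config: ModelConfig,
            labels: Optional[np.ndarray] = None) -> AccuracyDistribution:
    """Leave-one-out: N folds of train N-1 / test 1; a single accuracy."""
    x, y = _xy(table, labels)
    n = len(y)
    if n < 2:
        raise ValidationError("leave-one-out needs at least 2 samples")
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit(x[mask], y[mask], model_config)
        correct += int(predict(model, x[i:i + 1])[0] == y[i])
        mask[i] = True
    acc = correct / n
    return AccuracyDistribution(np.array([acc]), FoldScheme(kind="loo", n_iterations=1))


def _one_out_iteration(x: np.ndarray, y: np.ndarray, model_config: ModelConfig,
                       rng: np.random.Generator) -> float:
    """One iteration of the one-sample-per-participant-out scheme."""
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    m = counts[0]
    if not (counts == m).all():
        raise ValidationError(
            f"unequal replicate counts per participant: {dict(zip(classes, counts))}"
        )
    # assign each participant's samples to the m folds by random permutation
    fold_of = np.empty(len(y), dtype=int)
    for c in range(len(classes)):
        idx = np.flatnonzero(y_idx == c)
        fold_of[idx] = rng.permutation(m)
    correct = 0
    for f in range(m):
        test = fold_of == f
        model = fit(x[~test], y[~test], model_config)
        correct += int(np.sum(predict(model, x[test]) == y[test]))
    return correct / len(y)


def run_repeated_one_out_per_participant(
    table: EndpointTable,
    model_config: ModelConfig,
    n_iterations: int = 500,
    seed: int = 0,
    labels: Optional[np.ndarray] = None,
) -> AccuracyDistribution:
    """Repeated leave-one-sample-per-participant-out cross-validation.

    With 3 replicates on one day this is the 3-fold design that trains on 2
    samples per person and tests on the third; the fold assignment is redrawn
    independently every iteration.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    x, y = _xy(table, labels)
    accs = np.empty(n_iterations)
    for it in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        accs[it] = _one_out_iteration(x, y, model_config, rng)
    return AccuracyDistribution(
        accs, FoldScheme(kind="one_sample_per_participant_out",
                         n_iterations=n_iterations, seed=seed)
    )


def run_accumulated_days(
    table: EndpointTable,
    model_config: ModelConfig,
    day_sets: Optional[Sequence[Iterable[int]]] = None,
    n_iterations: int = 500,
    seed: int = 0,
) -> Mapping[tuple[int, ...], AccuracyDistribution]:
    """One-sample-per-participant-out CV on growing day windows.

    Default windows are days 1-2, 1-3, 1-4 and 1-5 of a 5-day cohort.  On a
    window of ``k`` days with ``r`` replicates/region/day the scheme has
    ``r * k`` folds: e.g. 2 days of 3 replicates -> 6 folds, training on 5
    and testing on 1 sample per person.
    """
    if day_sets is None:
        max_day = int(table.frame["day"].max())
        day_sets = [range(1, last + 1) for last in range(2, max_day + 1)]
    results = {}
    for i, days in enumerate(day_sets):
        days = tuple(sorted(int(d) for d in days))
        window = subset(table, days=days)
        results[days] = run_repeated_one_out_per_participant(
            window, model_config, n_iterations=n_iterations,
            seed=int(np.random.SeedSequence([seed, 10_000 + i]).generate_state(1)[0] % (2**31)),
        )
    return results


def run_across_day_holdout(
    table: EndpointTable,
    model_config: ModelConfig,
    train_days: Iterable[int],
    test_day: int,
    labels: Optional[np.ndarray] = None,
) -> float:
    """Fit on all body samples of *train_days*, report accuracy on *test_day*."""
    train_days = tuple(sorted(int(d) for d in train_days))
    test_day = int(test_day)
    if test_day in train_days:
        raise ValidationError(f"test day {test_day} must not appear in train days {train_days}")
    if not train_days:
        raise ValidationError("empty training-day set")
    x, y = _xy(table, labels)
    days = table.frame["day"].to_numpy(dtype=int)
    train = np.isin(days, train_days)
    test = days == test_day
    if not train.any():
        raise ValidationError(f"no samples in training days {train_days}")
    if not test.any():
        raise ValidationError(f"no samples in test day {test_day}")
    model = fit(x[train], y[train], model_config)
    return float(np.mean(predict(model, x[test]) == y[test]))
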