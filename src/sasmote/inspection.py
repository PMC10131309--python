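"""Self-inspection: score synthetic candidates by inspector disagreement.

The majority class is split into M near-equal random batches; each batch,
pooled with the full original minority class, trains one *inspector*
classifier on roughly balanced data.  M is the rounded majority/minority
ratio, so each batch is close to 1:1.  A candidate's uncertainty score is
the fraction of inspectors that call it majority:

    S(x) = (1/M) * sum_j 1[Rf_j(x) = majority]

Candidates scoring above the threshold T (default 0.5) are discarded as
indistinguishable from the majority class.  Inspectors are trained once,
on original data only — never on synthetic points, which would be
circular — and reused across all generation rounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data import LabeledDataset
from .exceptions import ConfigurationError, DataFormatError
from .sampler import SyntheticBatch

__all__ = [
    "InspectorEnsemble",
    "num_inspectors",
    "train_inspectors",
    "uncertainty_score",
    "filter_by_uncertainty",
]

DEFAULT_N_TREES = 100


@dataclass(frozen=True)
class InspectorEnsemble:
    """M fitted inspectors and the majority-batch partition behind them.

    ``batch_assignment`` holds M disjoint arrays of original majority row
    indices whose union is the full majority index set, sizes differing
    by at most one.  Inspector j was fitted on batch j plus all original
    minority rows.
    """

    inspectors: list
    batch_assignment: list
    majority_label: object

    @property
    def M(self) -> int:
        return len(self.inspectors)


def num_inspectors(minority_count: int, majority_count: int) -> int:
    """Number of inspectors: the majority/minority ratio, rounded half-up.

    Half-up keeps each majority batch as close to the minority size as an
    integer split allows; the floor of 1 covers balanced data.
    """
    if minority_count < 1:
        raise ConfigurationError("minority_count must be >= 1")
    if majority_count < minority_count:
        raise ConfigurationError("majority_count must be >= minority_count")
    return max(1, math.floor(majority_count / minority_count + 0.5))


def _default_inspector_factory(seed: int):
    return RandomForestClassifier(n_estimators=DEFAULT_N_TREES, random_state=seed)


def train_inspectors(
    ds: LabeledDataset,
    M: int,
    rng: np.random.Generator,
    classifier_factory=None,
) -> InspectorEnsemble:
    """Partition the majority class and fit one inspector per batch.

    Any classifier obeying the scikit-learn fit/predict contract may be
    plugged in through ``classifier_factory(seed) -> estimator``; the
    default is a 100-tree random forest.
    """
    if classifier_factory is None:
        classifier_factory = _default_inspector_factory
    minority_rows = ds.minority_indices
    majority_rows = ds.majority_indices
    if M < 1 or M > len(majority_rows):
        raise ConfigurationError(
            f"M must satisfy 1 <= M <= majority_count={len(majority_rows)}, got {M}"
        )
    shuffled = rng.permutation(majority_rows)
    batches = [np.sort(b) for b in np.array_split(shuffled, M)]

    inspectors = []
    for batch in batches:
        rows = np.concatenate([batch, minority_rows])
        clf = classifier_factory(int(rng.integers(0, 2**31 - 1)))
        clf.fit(ds.features[rows], ds.labels[rows])
        inspectors.append(clf)
    return InspectorEnsemble(
        inspectors=inspectors,
        batch_assignment=batches,
        majority_label=ds.majority_label,
    )


def uncertainty_score(ensemble: InspectorEnsemble, candidates) -> np.ndarray:
    """Per-candidate fraction of inspectors voting majority, in {0, 1/M, ..., 1}.

    ``candidates`` is a :class:`SyntheticBatch` or a raw point matrix.
    Hard class predictions feed the indicator; probabilities are never
    used.
    """
    X = candidates.points if isinstance(candidates, SyntheticBatch) else np.asarray(candidates)
    if X.shape[0] == 0:
        return np.zeros(0)
    n_expected = ensemble.inspectors[0].n_features_in_
    if X.shape[1] != n_expected:
        raise DataFormatError(
            f"candidates have {X.shape[1]} features, inspectors expect {n_expected}"
        )
    votes = np.stack(
        [clf.predict(X) == ensemble.majority_label for clf in ensemble.inspectors]
    )
    return votes.mean(axis=0)


def filter_by_uncertainty(
    candidates: SyntheticBatch, scores: np.ndarray, threshold: float
) -> SyntheticBatch:
    """Drop candidates whose score is strictly above the threshold.

    A score exactly equal to T is kept — only scores *higher than* the
    threshold mark low-quality points.  Order and provenance are
    preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must lie in [0, 1], got {threshold}")
    scores = np.asarray(scores)
    if len(scores) != len(candidates):
        raise DataFormatError("scores not aligned with candidates")
    return candidates.take(scores <= threshold)
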