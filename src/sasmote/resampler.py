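"""SASMOTE orchestration: neighbors -> generation -> inspection -> accumulate.

The self-inspected adaptive SMOTE resampler oversamples the minority
class of a binary dataset until the minority/majority ratio reaches a
target (default 50%).  Per round it (1) finds each minority point's k
nearest minority neighbors, (2) optionally restricts them to the visible
set, (3) interpolates N candidates per minority point, (4) optionally
filters candidates through the inspector ensemble, and (5) accumulates
the survivors.  Because inspection rejects an unpredictable fraction,
generation is iterated over rounds and the final round's surplus is
truncated by seeded uniform subsampling so the target count is hit
exactly whenever the round budget allows.

Ablation variants switch the two ingredients independently; with both off
the pipeline is classic SMOTE (uniform neighbor choice over the plain
KNN list, no rejection).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import LabeledDataset, class_counts, validate_dataset
from .exceptions import ConfigurationError
from .inspection import (
    filter_by_uncertainty,
    num_inspectors,
    train_inspectors,
    uncertainty_score,
)
from .neighbors import knn_minority, visible_neighbors
from .sampler import SyntheticBatch, generate_batch

__all__ = [
    "ResamplerConfig",
    "ResampleResult",
    "required_count",
    "fit_resample",
    "make_variant",
    "VARIANTS",
    "SASMOTE",
]

logger = logging.getLogger(__name__)

#: variant name -> (use_visible, use_inspection)
VARIANTS = {
    "sasmote": (True, True),
    "sasmote_no_visible": (False, True),
    "sasmote_no_inspection": (True, False),
    "smote": (False, False),
}


def _half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class ResamplerConfig:
    """Tuning parameters of one resampling run.

    k_frac
        Neighborhood size K as a fraction of the minority count; the
        integer k is ``max(1, round(k_frac * minority_count))``, clamped
        to ``minority_count - 1`` (a point is never its own neighbor).
    n_per_point
        Candidates generated per minority point per round (N).
    threshold
        Uncertainty cutoff T; candidates scoring strictly above it are
        discarded.
    target_ratio
        Desired minority/majority count ratio after resampling.
    use_visible, use_inspection
        The two SASMOTE ingredients; both off reproduces classic SMOTE.
    max_rounds
        Round budget before giving up on the target.
    seed
        Master seed; the entire run is reproducible from it.
    """

    k_frac: float = 0.75
    n_per_point: int = 5
    threshold: float = 0.5
    target_ratio: float = 0.5
    use_visible: bool = True
    use_inspection: bool = True
    max_rounds: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.k_frac <= 1.0:
            raise ConfigurationError(f"k_frac must lie in (0, 1], got {self.k_frac}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must lie in [0, 1], got {self.threshold}")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ConfigurationError(
                f"target_ratio must lie in (0, 1], got {self.target_ratio}"
            )
        if self.n_per_point < 1:
            raise ConfigurationError("n_per_point must be >= 1")
        if self.max_rounds < 1:
            raise ConfigurationError("max_rounds must be >= 1")

    def derive_k(self, minority_count: int) -> int:
        """Integer neighborhood size for a given minority count."""
        if minority_count < 2:
            raise ConfigurationError("minority class needs >= 2 samples")
        k = max(1, _half_up(self.k_frac * minority_count))
        return min(k, minority_count - 1)


@dataclass(frozen=True)
class RoundLog:
    round_index: int
    generated: int
    rejected: int
    accepted: int
    cumulative: int


@dataclass(frozen=True)
class ResampleResult:
    """Outcome of one resampling run.

    ``augmented_dataset`` holds the original rows unchanged and in order,
    followed by the accepted synthetic rows tagged with the minority
    label; ``accepted`` carries their provenance.
    """

    augmented_dataset: LabeledDataset
    accepted: SyntheticBatch
    rejected_count: int
    rounds_used: int
    achieved_ratio: float
    target_ratio: float
    round_log: list = field(default_factory=list)

    @property
    def target_reached(self) -> bool:
        return self.achieved_ratio >= self.target_ratio - 1e-12 or (
            # integer rounding can leave the ratio a hair under target
            abs(self.achieved_ratio - self.target_ratio)
            <= 1.0 / max(1, len(self.augmented_dataset.majority_indices))
        )


def required_count(minority_count: int, majority_count: int, target_ratio: float) -> int:
    """Synthetic points needed to lift the minority to the target ratio."""
    if not 0.0 < target_ratio <= 1.0:
        raise ConfigurationError(f"target_ratio must lie in (0, 1], got {target_ratio}")
    return max(0, math.ceil(target_ratio * majority_count) - minority_count)


def make_variant(name: str, **overrides) -> ResamplerConfig:
    """Config for one of the named variants.

    ``sasmote`` (visible + inspection), ``sasmote_no_visible``,
    ``sasmote_no_inspection``, ``smote``.  Dashes are accepted in place
    of underscores; other fields may be overridden by keyword.
    """
    key = name.replace("-", "_").lower()
    if key not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {name!r}; choose from {sorted(VARIANTS)}"
        )
    use_visible, use_inspection = VARIANTS[key]
    return ResamplerConfig(
        use_visible=use_visible, use_inspection=use_inspection, **overrides
    )


def fit_resample(ds: LabeledDataset, cfg: ResamplerConfig) -> ResampleResult:
    """Run the full resampling pipeline on a validated dataset.

    Reproducible from ``cfg.seed``.  If the round budget is exhausted
    before the target count is met, the result carries the shortfall
    (``achieved_ratio < target_ratio``) and a warning is emitted; this is
    not an error because a strict inspector on overlapping classes can
    legitimately reject almost everything.
    """
    ds = validate_dataset(ds, getattr(ds, "label_name", None))
    n_min, n_maj = class_counts(ds)
    need = required_count(n_min, n_maj, cfg.target_ratio)
    # independent streams so that disabling inspection (or making its filter
    # vacuous) leaves the generation draws untouched — the ablation variants
    # then coincide bit-for-bit with classic SMOTE under one seed
    seq_inspect, seq_sample = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = np.random.default_rng(seq_sample)
    rng_inspect = np.random.default_rng(seq_inspect)

    if need == 0:
        aug = ds
        return ResampleResult(
            augmented_dataset=aug,
            accepted=SyntheticBatch.empty(ds.n_features),
            rejected_count=0,
            rounds_used=0,
            achieved_ratio=n_min / n_maj,
            target_ratio=cfg.target_ratio,
        )

    k = cfg.derive_k(n_min)
    ni = knn_minority(ds, k)
    eligible = visible_neighbors(ni, ds) if cfg.use_visible else ni

    ensemble = None
    if cfg.use_inspection:
        M = num_inspectors(n_min, n_maj)
        ensemble = train_inspectors(ds, M, rng_inspect)

    accepted: list[SyntheticBatch] = []
    log: list[RoundLog] = []
    total = 0
    rejected_total = 0
    rounds_used = 0
    for rnd in range(1, cfg.max_rounds + 1):
        rounds_used = rnd
        batch = generate_batch(ds, eligible, cfg.n_per_point, rng, round_index=rnd)
        generated = len(batch)
        if ensemble is not None:
            scores = uncertainty_score(ensemble, batch)
            kept = filter_by_uncertainty(batch, scores, cfg.threshold)
        else:
            kept = batch
        rejected = generated - len(kept)
        rejected_total += rejected

        if total + len(kept) > need:
            # truncate the final round's surplus by uniform subsampling
            take = need - total
            sel = np.sort(rng.choice(len(kept), size=take, replace=False))
            kept = kept.take(sel)
        accepted.append(kept)
        total += len(kept)
        log.append(RoundLog(rnd, generated, rejected, len(kept), total))
        logger.info(
            "round %d: generated=%d rejected=%d accepted=%d cumulative=%d/%d",
            rnd, generated, rejected, len(kept), total, need,
        )
        if total >= need:
            break

    if total < need:
        warnings.warn(
            f"target unreachable: accepted {total}/{need} synthetic points "
            f"after {rounds_used} rounds",
            stacklevel=2,
        )

    all_accepted = (
        SyntheticBatch.concat(accepted) if accepted else SyntheticBatch.empty(ds.n_features)
    )
    aug_features = np.vstack([ds.features, all_accepted.points])
    aug_labels = np.concatenate(
        [ds.labels, np.full(len(all_accepted), ds.minority_label, dtype=ds.labels.dtype)]
    )
    origin = np.concatenate(
        [ds.origin, np.full(len(all_accepted), "synthetic", dtype=object)]
    )
    augmented = LabeledDataset(
        features=aug_features,
        labels=aug_labels,
        feature_names=ds.feature_names,
        label_name=ds.label_name,
        minority_label=ds.minority_label,
        majority_label=ds.majority_label,
        origin=origin,
    )
    return ResampleResult(
        augmented_dataset=augmented,
        accepted=all_accepted,
        rejected_count=rejected_total,
        rounds_used=rounds_used,
        achieved_ratio=(n_min + total) / n_maj,
        target_ratio=cfg.target_ratio,
        round_log=log,
    )


class SASMOTE:
    """Estimator-style front end with a ``fit_resample(X, y)`` interface.

    Thin wrapper over :func:`fit_resample` following the oversampler API
    convention familiar from imbalanced-learn::

        X_res, y_res = SASMOTE(seed=0).fit_resample(X, y)

    The functional API should be preferred when provenance, round logs or
    the rejected count are needed (see :attr:`last_result_`).
    """

    def __init__(self, variant: str = "sasmote", **config):
        self.variant = variant
        self.config = config
        self.last_result_: ResampleResult | None = None

    def fit_resample(self, X, y):
        import pandas as pd

        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        df["y"] = np.asarray(y)
        ds = validate_dataset(df, "y")
        cfg = make_variant(self.variant, **self.config)
        res = fit_resample(ds, cfg)
        self.last_result_ = res
        aug = res.augmented_dataset
        return aug.features, aug.labels
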