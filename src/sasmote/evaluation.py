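"""Cross-validated minority-class evaluation of resampling variants.

The harness mirrors the standard protocol for judging oversamplers:
stratified k-fold CV in which resampling touches the *training* split
only, a random-forest classifier is fitted on the augmented training
data, and minority-class precision, recall and F1 are measured on the
untouched test split.  Aggregates are the per-fold mean and sample
standard deviation.  One-at-a-time sensitivity sweeps over K (neighbor
fraction), N (samples per minority point) and T (uncertainty threshold)
reuse the same machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .data import LabeledDataset, class_counts
from .exceptions import ConfigurationError, DataFormatError
from .resampler import VARIANTS, ResamplerConfig, fit_resample

__all__ = [
    "EvaluationReport",
    "minority_metrics",
    "cross_validate",
    "sensitivity_sweep",
]

logger = logging.getLogger(__name__)

FINAL_N_TREES = 100  # same family/size as the inspectors, seeded independently


@dataclass(frozen=True)
class EvaluationReport:
    """Long-format results table plus run metadata.

    ``table`` columns: variant, parameter, value, fold, precision,
    recall, f1.  Per-fold rows have integer fold labels; aggregate rows
    use fold = "mean" and fold = "std" (sample standard deviation over
    folds, n-1 convention).
    """

    table: pd.DataFrame
    fold_count: int
    seed: int

    def aggregate(self, variant: str, parameter: str = "none", value="default"):
        """(mean, std) rows for one variant/setting as a small frame."""
        t = self.table
        sel = (
            (t["variant"] == variant)
            & (t["parameter"] == parameter)
            & (t["value"].astype(str) == str(value))
            & (t["fold"].isin(["mean", "std"]))
        )
        return t[sel].set_index("fold")[["precision", "recall", "f1"]]

    def mean_f1(self, variant: str, parameter: str = "none", value="default") -> float:
        return float(self.aggregate(variant, parameter, value).loc["mean", "f1"])

    @staticmethod
    def concat(reports: list["EvaluationReport"]) -> "EvaluationReport":
        return EvaluationReport(
            table=pd.concat([r.table for r in reports], ignore_index=True),
            fold_count=reports[0].fold_count,
            seed=reports[0].seed,
        )


def minority_metrics(true_labels, predicted_labels, minority_label):
    """Minority-class precision, recall and F1.

    Zero-denominator cases (no predicted positives, or no true
    positives) report 0 with a logged warning — the conservative
    convention for a minority-focused comparison.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise DataFormatError("label vectors differ in length")
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[minority_label], zero_division=0, warn_for=()
    )
    if (y_pred == minority_label).sum() == 0 or (y_true == minority_label).sum() == 0:
        logger.warning("zero denominator in minority metrics; reporting 0")
    return float(p[0]), float(r[0]), float(f1[0])


def _aggregate_rows(rows: list[dict], variant, parameter, value) -> list[dict]:
    sub = pd.DataFrame(rows)
    out = []
    for stat in ("mean", "std"):
        agg = getattr(sub[["precision", "recall", "f1"]], stat)(ddof=1) \
            if stat == "std" else sub[["precision", "recall", "f1"]].mean()
        out.append(
            {
                "variant": variant, "parameter": parameter, "value": value,
                "fold": stat, **agg.to_dict(),
            }
        )
    return out


def cross_validate(
    ds: LabeledDataset,
    variant: str,
    cfg: ResamplerConfig,
    folds: int = 5,
    seed: int = 0,
    parameter: str = "none",
    value="default",
) -> EvaluationReport:
    """Stratified k-fold evaluation of one variant on one dataset.

    ``variant`` is one of the resampler variants or ``"none"`` (no
    resampling baseline).  Resampling and classifier fitting see only the
    training split of each fold; the test split is untouched.
    """
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if variant != "none" and variant.replace("-", "_") not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    n_min, _ = class_counts(ds)
    if n_min < folds:
        raise ConfigurationError("too few minority samples for stratified folds")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for fold_idx, (train_rows, test_rows) in enumerate(
        skf.split(ds.features, ds.labels)
    ):
        train = ds.subset(train_rows)
        test = ds.subset(test_rows)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        if variant == "none":
            augmented = train
        else:
            use_visible, use_inspection = VARIANTS[variant.replace("-", "_")]
            fold_cfg = replace(
                cfg,
                use_visible=use_visible,
                use_inspection=use_inspection,
                seed=fold_seed,
            )
            augmented = fit_resample(train, fold_cfg).augmented_dataset
        clf = RandomForestClassifier(
            n_estimators=FINAL_N_TREES,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        clf.fit(augmented.features, augmented.labels)
        pred = clf.predict(test.features)
        p, r, f1 = minority_metrics(test.labels, pred, ds.minority_label)
        rows.append(
            {
                "variant": variant, "parameter": parameter, "value": value,
                "fold": fold_idx, "precision": p, "recall": r, "f1": f1,
            }
        )
    rows.extend(_aggregate_rows(rows, variant, parameter, value))
    return EvaluationReport(table=pd.DataFrame(rows), fold_count=folds, seed=seed)


def sensitivity_sweep(
    ds: LabeledDataset,
    grid: dict,
    variants,
    folds: int = 5,
    seed: int = 0,
    base_cfg: ResamplerConfig | None = None,
) -> EvaluationReport:
    """One-at-a-time parameter sweep around the default configuration.

    ``grid`` maps any of ``"k_frac"``, ``"n_per_point"``, ``"threshold"``
    to a list of values; each parameter is varied with the other two held
    at their defaults, for every requested variant.
    """
    if not grid:
        raise ConfigurationError("empty sweep grid")
    valid = {"k_frac", "n_per_point", "threshold"}
    unknown = set(grid) - valid
    if unknown:
        raise ConfigurationError(f"unknown sweep parameter(s): {sorted(unknown)}")
    base = base_cfg if base_cfg is not None else ResamplerConfig()
    reports = []
    for param, values in grid.items():
        for value in values:
            cfg = replace(base, **{param: value})
            for variant in variants:
                reports.append(
                    cross_validate(
                        ds, variant, cfg, folds=folds, seed=seed,
                        parameter=param, value=value,
                    )
                )
    return EvaluationReport.concat(reports)
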