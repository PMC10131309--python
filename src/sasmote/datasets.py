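"""Seeded synthetic imbalanced datasets with ground-truth class regions.

Three scenarios, each paired with a *membership oracle* — a deterministic
function mapping any point to the true generating region — so tests can
check where interpolated points actually land without external data:

``nonconvex_crescent``
    The minority class lives on a half-annulus (radius band
    ``[R - W, R + W]`` over the upper half-plane) wrapped around a
    majority Gaussian blob at the origin.  The minority support is
    nonconvex: the segment between the two crescent tips crosses the
    majority region, which is exactly the geometry where interpolating
    toward an invisible neighbor produces points inside the wrong class.

``gaussian_blobs``
    Two well-separated isotropic Gaussians (mean distance 8 x noise_sd),
    for sanity checks where nothing ambiguous should happen.

``overlap_blobs``
    Two isotropic Gaussians at 1.5 x noise_sd separation — heavy,
    controlled class overlap for end-to-end evaluation.  Under ~10%
    imbalance a classifier trained on the raw data predicts majority
    almost everywhere in the overlap, yielding the low minority recall
    that motivates oversampling in the first place.

Labels are 1 (minority) and 0 (majority).  Feature dimensions beyond the
first two are isotropic noise, so the geometry stays in-plane while
higher-dimensional code paths get exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LabeledDataset, class_counts, validate_dataset
from .exceptions import ConfigurationError

__all__ = ["SyntheticSpec", "generate", "ratio_sweep",
           "MINORITY_REGION", "MAJORITY_REGION"]

MINORITY_REGION = "minority_region"
MAJORITY_REGION = "majority_region"

SCENARIOS = ("nonconvex_crescent", "gaussian_blobs", "overlap_blobs")

# crescent geometry: annulus radius, band half-width
CRESCENT_R = 3.0
CRESCENT_W = 0.5
# blob mean separations in units of noise_sd; the overlap margin is set so
# that an unresampled classifier at ~10% imbalance shows the hallmark of the
# problem this package addresses — minority recall far below precision
OVERLAP_MARGIN = 1.5
SEPARATED_MARGIN = 8.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    scenario: str = "nonconvex_crescent"
    n_minority: int = 50
    n_majority: int = 500
    n_features: int = 2
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.n_minority < 1 or self.n_majority < 1:
            raise ConfigurationError("class counts must be positive")
        if self.n_minority > self.n_majority:
            raise ConfigurationError("n_minority must not exceed n_majority")
        if self.n_features < 2:
            raise ConfigurationError("need n_features >= 2")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


def _pad_noise(X2: np.ndarray, n_features: int, noise_sd: float,
               rng: np.random.Generator) -> np.ndarray:
    if n_features == 2:
        return X2
    extra = rng.normal(0.0, noise_sd, size=(X2.shape[0], n_features - 2))
    return np.hstack([X2, extra])


def _crescent_oracle(point) -> str:
    p = np.asarray(point, dtype=float)
    x, y = p[0], p[1]
    r = float(np.hypot(x, y))
    inside = y >= 0.0 and CRESCENT_R - CRESCENT_W <= r <= CRESCENT_R + CRESCENT_W
    return MINORITY_REGION if inside else MAJORITY_REGION


def _blob_oracle_factory(mu_min: np.ndarray, mu_maj: np.ndarray):
    def oracle(point) -> str:
        p = np.asarray(point, dtype=float)[:2]
        d_min = np.linalg.norm(p - mu_min)
        d_maj = np.linalg.norm(p - mu_maj)
        return MINORITY_REGION if d_min <= d_maj else MAJORITY_REGION

    return oracle


def generate(spec: SyntheticSpec):
    """Generate a dataset and its membership oracle.

    Returns
    -------
    ds : LabeledDataset
        Validated dataset, minority label 1, majority label 0.
    oracle : callable
        ``oracle(point) -> "minority_region" | "majority_region"`` using
        only the first two coordinates (the informative plane).
    """
    rng = np.random.default_rng(spec.seed)

    if spec.scenario == "nonconvex_crescent":
        theta = rng.uniform(0.0, np.pi, size=spec.n_minority)
        radius = rng.uniform(CRESCENT_R - CRESCENT_W, CRESCENT_R + CRESCENT_W,
                             size=spec.n_minority)
        minority = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        # majority blob sits in the concavity; 3 sigma inside the band
        blob_sd = (CRESCENT_R - CRESCENT_W) / 3.0
        majority = rng.normal(0.0, blob_sd, size=(spec.n_majority, 2))
        oracle = _crescent_oracle
    else:
        margin = SEPARATED_MARGIN if spec.scenario == "gaussian_blobs" else OVERLAP_MARGIN
        mu_min = np.array([margin * spec.noise_sd, 0.0])
        mu_maj = np.zeros(2)
        minority = rng.normal(0.0, spec.noise_sd, size=(spec.n_minority, 2)) + mu_min
        majority = rng.normal(0.0, spec.noise_sd, size=(spec.n_majority, 2)) + mu_maj
        oracle = _blob_oracle_factory(mu_min, mu_maj)

    X = np.vstack([minority, majority])
    X = _pad_noise(X, spec.n_features, spec.noise_sd, rng)
    y = np.concatenate(
        [np.ones(spec.n_minority, dtype=int), np.zeros(spec.n_majority, dtype=int)]
    )
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(spec.n_features)])
    df["label"] = y
    ds = validate_dataset(df, "label", minority_label=1)
    return ds, oracle


def ratio_sweep(ds: LabeledDataset, ratios, rng: np.random.Generator):
    """Down-sample one class to realize each requested imbalance ratio.

    For a ratio below the dataset's current minority/majority ratio the
    minority is down-sampled (to ``floor(ratio * majority)`` rows); for a
    ratio above it the majority is down-sampled; an equal ratio returns
    the dataset unchanged.  The non-down-sampled class keeps all rows.
    """
    n_min, n_maj = class_counts(ds)
    current = n_min / n_maj
    out = []
    for ratio in ratios:
        if not 0.0 < ratio <= 1.0:
            raise ConfigurationError(f"ratio must lie in (0, 1], got {ratio}")
        if np.isclose(ratio, current):
            out.append(ds)
            continue
        if ratio < current:
            keep_min = int(np.floor(ratio * n_maj))
            if keep_min < 1:
                raise ConfigurationError(f"ratio {ratio} leaves no minority rows")
            chosen = np.sort(rng.choice(ds.minority_indices, keep_min, replace=False))
            rows = np.sort(np.concatenate([chosen, ds.majority_indices]))
        else:
            keep_maj = int(np.floor(n_min / ratio))
            if keep_maj < n_min:
                raise ConfigurationError(f"ratio {ratio} not reachable by down-sampling")
            chosen = np.sort(rng.choice(ds.majority_indices, keep_maj, replace=False))
            rows = np.sort(np.concatenate([ds.minority_indices, chosen]))
        out.append(ds.subset(rows))
    return out
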