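"""Seeded synthetic patient cohorts for a two-class disease-detection problem.

Each record is a patient id, a fixed-length real feature vector and a binary
disease label.  Class 1 ("diseased") records are drawn with a standardized
mean shift (``effect_size``) on a configurable subset of informative features;
class 0 sits at baseline.  Features are min-max scaled to [0, 1] (an affine,
class-structure-preserving transform) because the downstream RBM treats
visible units as values in the unit interval, then snapped to a 10^-6
fixed-point grid so encrypted storage round-trips are bit-lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "PatientRecord",
    "CohortError",
    "generate_cohort",
    "split_cohort",
    "write_cohort",
    "read_cohort",
    "cohort_matrix",
]


class CohortError(ValueError):
    """Invalid cohort configuration, file content or split request."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic two-class cohort generator.

    Parameters
    ----------
    n_records : int
        Number of patients to generate.
    n_features : int
        Feature-vector length (default 5, the model's visible-layer width).
    class_balance : float
        Probability that a record is class 1; labels are Bernoulli draws, so
        the realized fraction varies within binomial sampling error.
    effect_size : float
        Standardized mean shift of class 1 on the informative features, in
        units of ``noise_sd``.
    noise_sd : float
        Per-feature Gaussian standard deviation.
    n_informative : int
        How many leading features carry the class signal.
    seed : int
        Generator seed; identical configs produce identical cohorts.
    """

    n_records: int
    n_features: int = 5
    class_balance: float = 0.5
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_informative: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise CohortError(f"n_records must be positive, got {self.n_records}")
        if self.n_features <= 0:
            raise CohortError(f"n_features must be positive, got {self.n_features}")
        if not 0.0 < self.class_balance < 1.0:
            raise CohortError("class_balance must lie in (0, 1)")
        if self.effect_size < 0.0:
            raise CohortError("effect_size must be nonnegative")
        if self.noise_sd <= 0.0:
            raise CohortError("noise_sd must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise CohortError("n_informative must lie in [0, n_features]")


@dataclass
class PatientRecord:
    """One subject: unique id, length-F feature vector, binary label."""

    patient_id: str
    features: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise CohortError("features must be a 1-D vector")
        if np.isnan(self.features).any():
            raise CohortError(f"record {self.patient_id} has missing features")
        if self.label not in (0, 1):
            raise CohortError(f"label must be 0 or 1, got {self.label!r}")


def generate_cohort(
    config: SyntheticConfig,
    *,
    scale: bool = True,
    quantize_decimals: int | None = 6,
) -> list[PatientRecord]:
    """Draw a seeded cohort with the configured class structure.

    Class-conditional features are Gaussian: class 0 at baseline 0, class 1
    shifted by ``effect_size * noise_sd`` on the first ``n_informative``
    features.  With ``scale`` (default) every feature is min-max scaled to
    [0, 1] and snapped to the 10^-quantize_decimals grid.  Deterministic
    given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n, f = config.n_records, config.n_features
    labels = (rng.random(n) < config.class_balance).astype(int)
    x = rng.normal(0.0, config.noise_sd, size=(n, f))
    shift = config.effect_size * config.noise_sd
    x[labels == 1, : config.n_informative] += shift

    if scale:
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        span = hi - lo
        degenerate = span == 0.0
        span[degenerate] = 1.0
        x = (x - lo) / span
        x[:, degenerate] = 0.5
        if quantize_decimals is not None:
            grid = 10.0**quantize_decimals
            x = np.round(x * grid) / grid

    width = max(6, len(str(n)))
    return [
        PatientRecord(patient_id=f"P{i:0{width}d}", features=x[i], label=int(labels[i]))
        for i in range(n)
    ]


def split_cohort(
    records: list[PatientRecord],
    train_fraction: float,
    seed: int,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Seeded stratified train/test split.

    The partition is disjoint and exhaustive; shuffling happens within each
    label stratum, and whenever a stratum has at least two members both sides
    receive at least one of them.
    """
    n = len(records)
    if n < 2:
        raise CohortError("need at least 2 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise CohortError("train_fraction must lie in (0, 1)")
    n_train = int(round(n * train_fraction))
    if n_train <= 0 or n_train >= n:
        raise CohortError(
            f"train_fraction {train_fraction} leaves an empty side for {n} records"
        )

    rng = np.random.default_rng(seed)
    labels = np.array([r.label for r in records])
    strata = [np.flatnonzero(labels == c) for c in sorted(set(labels.tolist()))]

    # Largest-remainder allocation of n_train across strata, then clamp so
    # that no stratum of size >= 2 ends up entirely on one side.
    ideals = [len(s) * train_fraction for s in strata]
    counts = [int(np.floor(v)) for v in ideals]
    remainders = [v - c for v, c in zip(ideals, counts)]
    for idx in sorted(
        range(len(strata)), key=lambda i: (-remainders[i], -len(strata[i]))
    ):
        if sum(counts) >= n_train:
            break
        counts[idx] += 1
    # settle rounding drift
    i = 0
    while sum(counts) != n_train:
        j = i % len(strata)
        if sum(counts) < n_train and counts[j] < len(strata[j]):
            counts[j] += 1
        elif sum(counts) > n_train and counts[j] > 0:
            counts[j] -= 1
        i += 1
    for j, s in enumerate(strata):
        if len(s) >= 2:
            counts[j] = min(max(counts[j], 1), len(s) - 1)

    train_idx: list[int] = []
    test_idx: list[int] = []
    for s, c in zip(strata, counts):
        perm = rng.permutation(len(s))
        train_idx.extend(s[perm[:c]].tolist())
        test_idx.extend(s[perm[c:]].tolist())
    train_idx.sort()
    test_idx.sort()
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write a cohort as CSV with header ``patient_id,f1..fF,label``.

    Feature values are serialized with Python's shortest round-tripping float
    representation, so ``read_cohort(write_cohort(...))`` is bit-exact.
    """
    if records:
        n_features = len(records[0].features)
    else:
        n_features = 0
    cols = ["patient_id"] + [f"f{i + 1}" for i in range(n_features)] + ["label"]
    rows = []
    for r in records:
        rows.append([r.patient_id] + [repr(float(v)) for v in r.features] + [r.label])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort`.

    Raises :class:`CohortError` naming the offending row for duplicate ids,
    non-numeric features or missing columns.  A header-only file yields an
    empty cohort with a logged warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns or "label" not in df.columns:
        raise CohortError(f"{path}: missing required column (patient_id/label)")
    feature_cols = [c for c in df.columns if c not in ("patient_id", "label")]
    if df.empty:
        logger.warning("%s: header-only cohort file, returning empty cohort", path)
        return []

    seen: set[str] = set()
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        pid = getattr(row, "patient_id")
        if pid in seen:
            raise CohortError(f"{path}: duplicate patient_id {pid!r} at row {i}")
        seen.add(pid)
        try:
            feats = np.array(
                [float(getattr(row, c)) for c in feature_cols], dtype=float
            )
        except ValueError as exc:
            raise CohortError(f"{path}: non-numeric feature at row {i}: {exc}") from exc
        if np.isnan(feats).any():
            raise CohortError(f"{path}: missing feature value at row {i}")
        raw_label = getattr(row, "label")
        try:
            label = int(raw_label)
        except ValueError as exc:
            raise CohortError(f"{path}: non-integer label at row {i}") from exc
        if label not in (0, 1):
            raise CohortError(f"{path}: label must be 0/1 at row {i}, got {label}")
        records.append(PatientRecord(patient_id=pid, features=feats, label=label))
    return records


def cohort_matrix(records: list[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a cohort into a feature matrix (N, F) and label vector (N,)."""
    if not records:
        raise CohortError("empty cohort")
    x = np.stack([r.features for r in records])
    y = np.array([r.label for r in records], dtype=int)
    return x, y
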