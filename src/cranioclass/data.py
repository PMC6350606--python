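"""Craniometric measurement tables.

The unit of analysis is one skull described by six midsagittal
measurements — cranial, apical (parietal) and occipital sagittal arcs and
their chords — plus a binary sex label. This module owns CSV ingestion,
train/test splitting, and feature normalization; everything downstream
(networks, boosting, baselines) consumes the :class:`MeasurementDataset`
it produces.

Label coding is female = 1, male = 0 at the scalar level; the two-neuron
network output uses the one-hot form female = (1, 0), male = (0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    DataFormatError,
    DegenerateFeatureError,
    MeasurementParseError,
    MissingColumnError,
    StratificationError,
)

#: Canonical feature order: cranial/apical/occipital sagittal arc and chord.
FEATURES: tuple[str, ...] = ("CSA", "CSC", "ASA", "ASC", "OSA", "OSC")

FEMALE: int = 1
MALE: int = 0

TRAIN = "train"
TEST = "test"

_SEX_ALIASES = {
    "F": FEMALE, "FEMALE": FEMALE, "1": FEMALE,
    "M": MALE, "MALE": MALE, "0": MALE,
}


def _parse_sex(value: object, row: int) -> int:
    token = str(value).strip().upper()
    if token not in _SEX_ALIASES:
        raise MeasurementParseError(row, "sex", f"unrecognized sex label {value!r}")
    return _SEX_ALIASES[token]


@dataclass(frozen=True)
class CraniometricRecord:
    """One skull: six strictly positive measurements and a sex label."""

    csa: float
    csc: float
    asa: float
    asc: float
    osa: float
    osc: float
    sex: int

    def __post_init__(self) -> None:
        for name in FEATURES:
            value = getattr(self, name.lower())
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise DataFormatError(f"measurement {name} must be finite, got {value!r}")
            if value <= 0:
                raise DataFormatError(f"measurement {name} must be strictly positive, got {value!r}")
        if self.sex not in (FEMALE, MALE):
            raise DataFormatError(f"sex must be {FEMALE} (female) or {MALE} (male), got {self.sex!r}")

    @property
    def values(self) -> np.ndarray:
        return np.array([getattr(self, name.lower()) for name in FEATURES], dtype=float)


@dataclass(frozen=True)
class Normalization:
    """A per-feature affine map ``(x - loc) / scale`` and its inverse.

    ``minmax`` mode uses (train min, train range); ``zscore`` uses
    (train mean, train sd with ddof=1).
    """

    mode: str
    loc: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.loc) / self.scale

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return X * self.scale + self.loc


@dataclass
class MeasurementDataset:
    """A measurement matrix with optional split labels and normalization state.

    ``X`` is ``(n, 6)`` float64 in the :data:`FEATURES` column order; ``sex``
    is ``(n,)`` with female = 1, male = 0. ``split`` holds ``"train"`` /
    ``"test"`` per row once a split has been assigned. When
    ``normalization`` is set, ``X`` is already in normalized units.
    """

    X: np.ndarray
    sex: np.ndarray
    split: np.ndarray | None = None
    normalization: Normalization | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURES):
            raise DataFormatError(f"X must be (n, {len(FEATURES)}), got {self.X.shape}")
        if self.sex.shape != (self.X.shape[0],):
            raise DataFormatError("sex labels must align with measurement rows")
        if not np.isin(self.sex, (FEMALE, MALE)).all():
            raise DataFormatError("sex labels must be 0 (male) or 1 (female)")

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[CraniometricRecord]) -> "MeasurementDataset":
        records = list(records)
        if not records:
            raise DataFormatError("dataset must contain at least one record")
        X = np.stack([r.values for r in records])
        sex = np.array([r.sex for r in records], dtype=int)
        return cls(X=X, sex=sex)

    @property
    def records(self) -> list[CraniometricRecord]:
        """Rows as records (only meaningful on original-scale data)."""
        return [
            CraniometricRecord(*map(float, row), sex=int(s))
            for row, s in zip(self.X, self.sex)
        ]

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_female(self) -> int:
        return int((self.sex == FEMALE).sum())

    @property
    def n_male(self) -> int:
        return int((self.sex == MALE).sum())

    def mask(self, split: str) -> np.ndarray:
        if self.split is None:
            raise DataFormatError("no train/test split has been assigned")
        if split not in (TRAIN, TEST):
            raise DataFormatError(f"split must be 'train' or 'test', got {split!r}")
        return self.split == split

    def subset_arrays(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.mask(split)
        if not m.any():
            raise DataFormatError(f"the {split} split is empty")
        return self.X[m], self.sex[m]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(FEATURES))
        frame["sex"] = self.sex
        if self.split is not None:
            frame["split"] = self.split
        return frame


def one_hot(sex: np.ndarray) -> np.ndarray:
    """One-hot targets over (female, male) output neurons."""
    sex = np.asarray(sex, dtype=float)
    return np.column_stack([sex, 1.0 - sex])


# -- CSV ingestion / export -------------------------------------------


def read_measurements(path, delimiter: str = ",") -> MeasurementDataset:
    """Read a measurement table from CSV.

    The header must name the six measurement columns (case-insensitive)
    and a ``sex`` column accepting {F, M} or {1, 0}. Unparseable or
    non-positive measurements are rejected with a 1-based data-row index.
    """
    try:
        frame = pd.read_csv(path, delimiter=delimiter, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise DataFormatError(f"could not parse CSV {path}: {exc}") from exc

    colmap = {c.strip().upper(): c for c in frame.columns}
    for name in FEATURES:
        if name not in colmap:
            raise MissingColumnError(name)
    if "SEX" not in colmap:
        raise MissingColumnError("sex")

    n = len(frame)
    X = np.empty((n, len(FEATURES)))
    for j, name in enumerate(FEATURES):
        col = frame[colmap[name]]
        for i in range(n):
            cell = col.iloc[i]
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise MeasurementParseError(i + 1, name, f"non-numeric value {cell!r}") from None
            if not math.isfinite(value):
                raise MeasurementParseError(i + 1, name, f"non-finite value {cell!r}")
            if value <= 0:
                raise MeasurementParseError(i + 1, name, f"non-positive measurement {value!r}")
            X[i, j] = value
    sex = np.array([_parse_sex(v, i + 1) for i, v in enumerate(frame[colmap["SEX"]])])

    dataset = MeasurementDataset(X=X, sex=sex)
    if "SPLIT" in colmap:
        split = frame[colmap["SPLIT"]].str.strip().str.lower().to_numpy()
        if not np.isin(split, (TRAIN, TEST)).all():
            raise DataFormatError("split column must contain only 'train'/'test'")
        dataset.split = split
    return dataset


def write_measurements(dataset: MeasurementDataset, path, delimiter: str = ",") -> None:
    """Write the dataset in the same CSV dialect (plus a split column if assigned)."""
    dataset.to_frame().to_csv(path, sep=delimiter, index=False)


# -- splitting ---------------------------------------------------------


def split_train_test(
    dataset: MeasurementDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> MeasurementDataset:
    """Assign a deterministic train/test split.

    Stratified (the default) draws ``round(class_size * fraction)`` training
    rows per class so the class ratio is preserved to within one record;
    e.g. 153 females / 114 males at fraction 0.7 gives 107 + 80 = 187
    training and 80 testing rows.
    """
    if not 0 < train_fraction < 1:
        raise DataFormatError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = len(dataset)
    rng = np.random.default_rng(seed)
    split = np.full(n, TEST, dtype=object)
    if stratified:
        for label in (FEMALE, MALE):
            idx = np.flatnonzero(dataset.sex == label)
            if idx.size == 0:
                name = "female" if label == FEMALE else "male"
                raise StratificationError(f"cannot stratify: no {name} records")
            k = int(np.rint(idx.size * train_fraction))
            chosen = rng.permutation(idx)[:k]
            split[chosen] = TRAIN
    else:
        k = int(np.rint(n * train_fraction))
        split[rng.permutation(n)[:k]] = TRAIN
    return replace(dataset, split=np.asarray(split, dtype=object))


# -- normalization -----------------------------------------------------


def normalize(dataset: MeasurementDataset, mode: str = "minmax") -> MeasurementDataset:
    """Normalize features using parameters fitted on the training rows only.

    ``minmax`` maps each training feature onto [0, 1] (test rows may fall
    outside); ``zscore`` centers and scales by the training mean and sd.
    The fitted parameters are stored for exact inversion.
    """
    if mode not in ("minmax", "zscore"):
        raise DataFormatError(f"unknown normalization mode {mode!r}")
    Xtr, _ = dataset.subset_arrays(TRAIN)
    if mode == "minmax":
        loc = Xtr.min(axis=0)
        scale = Xtr.max(axis=0) - loc
    else:
        loc = Xtr.mean(axis=0)
        scale = Xtr.std(axis=0, ddof=1)
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        raise DegenerateFeatureError(FEATURES[bad[0]])
    norm = Normalization(mode=mode, loc=loc, scale=scale)
    return replace(dataset, X=norm.transform(dataset.X), normalization=norm)


def denormalize(dataset: MeasurementDataset) -> MeasurementDataset:
    """Invert :func:`normalize`, restoring original measurement units."""
    if dataset.normalization is None:
        raise DataFormatError("dataset carries no normalization to invert")
    return replace(dataset, X=dataset.normalization.inverse(dataset.X), normalization=None)


def strip(dataset: MeasurementDataset) -> MeasurementDataset:
    """Return the raw dataset: original units, no split assignment."""
    if dataset.normalization is not None:
        dataset = denormalize(dataset)
    return replace(dataset, split=None)
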