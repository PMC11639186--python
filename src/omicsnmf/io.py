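"""Reading, validation, alignment and splitting of expression matrices.

An :class:`OmicsMatrix` holds one modality as a non-negative samples x
features matrix with string identifiers on both axes.  A
:class:`PairedOmicsDataset` aligns a source modality (n samples) with a
target modality measured on a subset of m <= n of those samples; the k = n - m
samples present only in the source are the ones whose target rows are to be
imputed.  A :class:`SplitPlan` partitions the m observed samples into training
and validation sets for one repetition of the experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "PairedOmicsDataset",
    "SplitPlan",
    "read_expression_matrix",
    "write_expression_matrix",
    "log2p1_transform",
    "align_samples",
    "make_split",
    "hold_out_missing",
]


class ValidationError(ValueError):
    """Raised when an input matrix or table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class OmicsMatrix:
    """One omics modality: samples x features, non-negative and finite.

    Parameters
    ----------
    sample_ids, feature_ids:
        Ordered, unique string identifiers for rows and columns.
    values:
        Real matrix of shape ``(len(sample_ids), len(feature_ids))`` with all
        entries finite and >= 0 (non-negativity is required downstream by the
        NMF decomposition).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[r]!r}, "
                f"feature {self.feature_ids[c]!r}"
            )
        neg = self.values < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative value {self.values[r, c]} at sample "
                f"{self.sample_ids[r]!r}, feature {self.feature_ids[c]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, ids: Sequence[str]) -> "OmicsMatrix":
        """Rows restricted to ``ids``, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValidationError(f"unknown sample identifiers: {missing}")
        rows = [index[i] for i in ids]
        return OmicsMatrix(list(ids), list(self.feature_ids), self.values[rows])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OmicsMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class PairedOmicsDataset:
    """Aligned source (n x p) and target (m x q) matrices.

    ``observed_ids`` are the m samples measured in both modalities (row order
    of ``source`` restricted to them matches ``target``); ``missing_ids`` are
    the k = n - m samples with a source profile but no target profile.
    """

    source: OmicsMatrix
    target: OmicsMatrix
    observed_ids: list[str]
    missing_ids: list[str]

    def __post_init__(self) -> None:
        src = set(self.source.sample_ids)
        tgt = set(self.target.sample_ids)
        if not tgt <= src:
            raise ValidationError(
                f"target samples absent from source: {sorted(tgt - src)}"
            )
        if set(self.observed_ids) != tgt:
            raise ValidationError("observed_ids must equal the target sample set")
        if set(self.missing_ids) != src - tgt:
            raise ValidationError("missing_ids must equal source \\ target samples")
        if self.observed_ids != self.target.sample_ids:
            raise ValidationError("observed_ids must follow target row order")
        assert self.k == self.n - self.m

    @property
    def n(self) -> int:
        return self.source.n_samples

    @property
    def m(self) -> int:
        return self.target.n_samples

    @property
    def k(self) -> int:
        return len(self.missing_ids)

    def source_rows(self, ids: Sequence[str]) -> np.ndarray:
        return self.source.subset_samples(ids).values

    def target_rows(self, ids: Sequence[str]) -> np.ndarray:
        return self.target.subset_samples(ids).values


@dataclass
class SplitPlan:
    """One train/validation partition of the observed samples."""

    train_ids: list[str]
    validation_ids: list[str]
    missing_ids: list[str]
    split_seed: int
    train_fraction: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.validation_ids):
            raise ValidationError("train and validation sets overlap")

    @property
    def observed_ids(self) -> list[str]:
        return self.train_ids + self.validation_ids

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_ids": self.train_ids,
                    "validation_ids": self.validation_ids,
                    "missing_ids": self.missing_ids,
                    "split_seed": self.split_seed,
                    "train_fraction": self.train_fraction,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            d["train_ids"],
            d["validation_ids"],
            d["missing_ids"],
            d["split_seed"],
            d["train_fraction"],
        )


def read_expression_matrix(
    path: str | Path,
    orientation: str = "samples_by_features",
    delimiter: str = "\t",
) -> OmicsMatrix:
    """Read a delimited expression table into an :class:`OmicsMatrix`.

    The first header field is treated as a corner label and ignored.  With
    ``orientation="features_by_samples"`` (the common distribution format for
    expression hubs) the table is transposed on read so the in-memory
    orientation is always samples x features.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    if orientation == "features_by_samples":
        df = df.T
    values = df.to_numpy(dtype=float)
    return OmicsMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_expression_matrix(
    m: OmicsMatrix,
    path: str | Path,
    orientation: str = "samples_by_features",
    delimiter: str = "\t",
) -> None:
    """Round-trip safe writer (full float precision, repr-based)."""
    df = m.to_frame()
    if orientation == "features_by_samples":
        df = df.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=delimiter, float_format="%.17g", index_label="id")


def log2p1_transform(m: OmicsMatrix) -> OmicsMatrix:
    """Apply ``log2(x + 1)`` elementwise (the standard expression transform)."""
    return OmicsMatrix(list(m.sample_ids), list(m.feature_ids), np.log2(m.values + 1.0))


def align_samples(source: OmicsMatrix, target: OmicsMatrix) -> PairedOmicsDataset:
    """Pair a source and a target modality on their shared samples.

    Every target sample must exist in the source.  Observed samples keep the
    target's row order; missing samples keep the source's row order.
    """
    src_set = set(source.sample_ids)
    absent = [s for s in target.sample_ids if s not in src_set]
    if absent:
        raise ValidationError(f"target samples absent from source: {absent}")
    observed = list(target.sample_ids)
    tgt_set = set(observed)
    missing = [s for s in source.sample_ids if s not in tgt_set]
    return PairedOmicsDataset(source, target, observed, missing)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_split(ds: PairedOmicsDataset, train_fraction: float, seed: int) -> SplitPlan:
    """Seeded train/validation partition of the observed samples."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if ds.m < 2:
        raise ValueError("need at least 2 observed samples to split")
    n_train = _round_half_up(train_fraction * ds.m)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.m)
    obs = ds.observed_ids
    train = [obs[i] for i in perm[:n_train]]
    val = [obs[i] for i in perm[n_train:]]
    return SplitPlan(train, val, list(ds.missing_ids), seed, train_fraction)


def hold_out_missing(
    ds: PairedOmicsDataset, fraction: float, seed: int
) -> tuple[PairedOmicsDataset, OmicsMatrix]:
    """Move a seeded fraction of observed samples into the missing set.

    Emulates the "assumed missing" evaluation protocol: the held-out samples'
    target rows are removed from the dataset and returned separately as ground
    truth, so the trainer can never see them.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n_hold = _round_half_up(fraction * ds.m)
    if n_hold == 0:
        raise ValueError("fraction too small: no samples would be held out")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.m)
    obs = ds.observed_ids
    held = {obs[i] for i in perm[:n_hold]}
    kept_ids = [s for s in obs if s not in held]
    held_ids = [s for s in obs if s in held]
    truth = ds.target.subset_samples(held_ids)
    new_target = ds.target.subset_samples(kept_ids)
    new_ds = align_samples(ds.source, new_target)
    return new_ds, truth
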