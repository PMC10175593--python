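"""Replicate averaging and column pretreatment (centering / autoscaling).

Pretreatment models follow the fit/apply split used throughout
chemometrics so cross-validation can refit the transform on each
training fold and never leak test-row statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .data_model import DataError, SensorBlock

PRETREATMENTS = ("center", "autoscale", "none")


@dataclass(frozen=True)
class CenteringModel:
    """Stored column means (and, for autoscaling, standard deviations)."""

    means: np.ndarray
    stds: np.ndarray | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        if self.stds is not None:
            stds = np.asarray(self.stds, dtype=float)
            if stds.shape != self.means.shape:
                raise DataError("stds and means must have equal length")
            object.__setattr__(self, "stds", stds)

    @property
    def n_vars(self) -> int:
        return self.means.shape[0]


def fit_center(
    X: np.ndarray, *, scale: bool = False, source: str | None = None
) -> CenteringModel:
    """Fit a mean-centering (optionally autoscaling) model on training rows.

    Standard deviations use the n-1 denominator. A zero-variance column
    is an error when scaling is requested.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    stds = None
    if scale:
        stds = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(stds <= 0)
        if zero.size:
            raise DataError(f"zero-variance column(s) {zero.tolist()} cannot be autoscaled")
    return CenteringModel(means=means, stds=stds, source=source)


def apply_center(model: CenteringModel, X: np.ndarray) -> np.ndarray:
    """Apply stored means (and stds) to new rows; never recomputes."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.n_vars:
        raise DataError(f"expected {model.n_vars} columns, got {X.shape[-1]}")
    out = X - model.means
    if model.stds is not None:
        out = out / model.stds
    return out


def invert_center(model: CenteringModel, X: np.ndarray) -> np.ndarray:
    """Undo :func:`apply_center` (exact reconstruction)."""
    X = np.asarray(X, dtype=float)
    if model.stds is not None:
        X = X * model.stds
    return X + model.means


def fit_pretreatment(
    X: np.ndarray, mode: str = "center", source: str | None = None
) -> CenteringModel | None:
    """Dispatch on a pretreatment mode name; ``none`` returns ``None``."""
    if mode == "none":
        return None
    if mode == "center":
        return fit_center(X, scale=False, source=source)
    if mode == "autoscale":
        return fit_center(X, scale=True, source=source)
    raise DataError(f"unknown pretreatment {mode!r}; expected one of {PRETREATMENTS}")


def apply_pretreatment(model: CenteringModel | None, X: np.ndarray) -> np.ndarray:
    if model is None:
        return np.asarray(X, dtype=float)
    return apply_center(model, X)


def average_replicates(
    block: SensorBlock, replicate_map: Mapping[str, Sequence[str]]
) -> SensorBlock:
    """Collapse replicate rows into one arithmetic-mean row per sample.

    ``replicate_map`` maps each output sample id to the list of row ids
    in ``block`` that are its replicates; the groups must partition the
    block's rows.
    """
    row_index = {sid: i for i, sid in enumerate(block.sample_ids)}
    used: set[int] = set()
    out_ids: list[str] = []
    rows: list[np.ndarray] = []
    for sample_id, members in replicate_map.items():
        if not members:
            raise DataError(f"replicate group {sample_id!r} is empty")
        idx = []
        for member in members:
            if member not in row_index:
                raise DataError(f"replicate row {member!r} not in block {block.source}")
            i = row_index[member]
            if i in used:
                raise DataError(f"row {member!r} referenced by more than one group")
            used.add(i)
            idx.append(i)
        out_ids.append(sample_id)
        rows.append(block.values[idx].mean(axis=0))
    if len(used) != block.n_samples:
        missing = [sid for sid in block.sample_ids if row_index[sid] not in used]
        raise DataError(f"rows not covered by any replicate group: {missing}")
    return replace(
        block, sample_ids=tuple(out_ids), values=np.vstack(rows)
    )
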