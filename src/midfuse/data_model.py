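"""Domain containers for multi-block sensor panels.

A panel couples up to four instrument blocks measured on the same
samples: electronic nose (EN, gas-sensor responses), electronic tongue
(ET, taste-sensor responses), electronic eye (EE, color-number counts)
and near-infrared spectra (NIR, absorbance on a wavenumber grid).
Blocks are stored as samples x variables matrices; labels carry both an
authenticity tag (authentic FC vs counterfeit) and a species tag
(FU / FP / FD for the authentic species, FUS for the counterfeit).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("EN", "ET", "EE", "NIR")

AUTHENTIC = "FC"
COUNTERFEIT = "COUNTERFEIT"
AUTHENTIC_SPECIES = ("FU", "FP", "FD")
COUNTERFEIT_SPECIES = ("FUS",)
SPECIES = AUTHENTIC_SPECIES + COUNTERFEIT_SPECIES

TASKS = ("authenticity", "species")


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class SensorBlock:
    """One instrument's samples x variables matrix.

    Parameters
    ----------
    source : str
        Instrument tag, one of ``EN``, ``ET``, ``EE``, ``NIR``.
    sample_ids : tuple of str
        Row identifiers, in matrix order.
    var_names : tuple of str
        Column identifiers (for NIR: wavenumber in cm^-1 as a string).
    values : ndarray of shape (n_samples, n_vars)
    """

    source: str
    sample_ids: tuple[str, ...]
    var_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise DataError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "var_names", tuple(str(v) for v in self.var_names))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        object.__setattr__(self, "values", values)
        n, p = values.shape
        if n != len(self.sample_ids):
            raise DataError(
                f"{self.source}: {n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.var_names):
            raise DataError(
                f"{self.source}: {p} columns but {len(self.var_names)} variable names"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError(f"{self.source}: duplicate sample ids")
        if len(set(self.var_names)) != len(self.var_names):
            raise DataError(f"{self.source}: duplicate variable names")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"{self.source}: non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, variable {self.var_names[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids: Sequence[str]) -> "SensorBlock":
        """Return a block restricted to ``ids``, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise DataError(f"{self.source}: sample {exc.args[0]!r} not in block") from exc
        return replace(self, sample_ids=tuple(ids), values=self.values[rows])

    def subset_vars(self, indices: Sequence[int]) -> "SensorBlock":
        """Return a block restricted to the variable columns ``indices``."""
        idx = list(indices)
        return replace(
            self,
            var_names=tuple(self.var_names[j] for j in idx),
            values=self.values[:, idx],
        )


@dataclass(frozen=True)
class LabelTable:
    """Per-sample authenticity and species labels.

    The consistency invariant of the study design is enforced: species
    FUS is the counterfeit, the three Fritillaria cirrhosae source
    species (FU, FP, FD) are authentic.
    """

    sample_ids: tuple[str, ...]
    authenticity: tuple[str, ...]
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "authenticity", tuple(self.authenticity))
        object.__setattr__(self, "species", tuple(self.species))
        n = len(self.sample_ids)
        if len(self.authenticity) != n or len(self.species) != n:
            raise DataError("label columns must have equal length")
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample ids in label table")
        for sid, auth, sp in zip(self.sample_ids, self.authenticity, self.species):
            if auth not in (AUTHENTIC, COUNTERFEIT):
                raise DataError(f"sample {sid!r}: unknown authenticity {auth!r}")
            if sp not in SPECIES:
                raise DataError(f"sample {sid!r}: unknown species {sp!r}")
            if sp in COUNTERFEIT_SPECIES and auth != COUNTERFEIT:
                raise DataError(
                    f"sample {sid!r}: species {sp} implies counterfeit, got {auth}"
                )
            if sp in AUTHENTIC_SPECIES and auth != AUTHENTIC:
                raise DataError(
                    f"sample {sid!r}: species {sp} implies authentic ({AUTHENTIC}), got {auth}"
                )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def labels_for(self, task: str) -> tuple[str, ...]:
        if task == "authenticity":
            return self.authenticity
        if task == "species":
            return self.species
        raise DataError(f"unknown task {task!r}; expected one of {TASKS}")

    def subset(self, ids: Sequence[str]) -> "LabelTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return LabelTable(
            sample_ids=tuple(ids),
            authenticity=tuple(self.authenticity[i] for i in rows),
            species=tuple(self.species[i] for i in rows),
        )


@dataclass(frozen=True)
class FusionDataset:
    """Aligned sensor blocks plus labels for one classification task."""

    blocks: dict[str, SensorBlock]
    labels: LabelTable
    task: str

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise DataError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if not self.blocks:
            raise DataError("dataset needs at least one block")
        ids = self.labels.sample_ids
        for source, block in self.blocks.items():
            if block.sample_ids != ids:
                raise DataError(
                    f"block {source} sample order differs from label order; "
                    "use assemble_dataset to align"
                )
        if len(set(self.y)) < 2:
            raise DataError(f"task {self.task!r} has fewer than 2 classes present")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.labels.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def y(self) -> tuple[str, ...]:
        """Class labels for the active task."""
        return self.labels.labels_for(self.task)

    def with_blocks(self, sources: Sequence[str]) -> "FusionDataset":
        """Dataset restricted to the given block sources (order kept canonical)."""
        missing = [s for s in sources if s not in self.blocks]
        if missing:
            raise DataError(f"blocks not present in dataset: {missing}")
        kept = {s: self.blocks[s] for s in SOURCES if s in sources}
        return FusionDataset(blocks=kept, labels=self.labels, task=self.task)


def load_block(path: str | Path, source: str) -> SensorBlock:
    """Read a sensor block from a CSV file.

    The file has a header row of variable names; the first column holds
    sample ids. Decimal separator is the dot regardless of locale.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype={0: str})
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        row, col = next(zip(*np.where(body.isna().to_numpy())))
        raise DataError(
            f"{path.name}: non-numeric cell at sample {df.index[row]!r}, "
            f"variable {df.columns[col]!r}"
        )
    return SensorBlock(
        source=source,
        sample_ids=tuple(str(s) for s in df.index),
        var_names=tuple(str(c) for c in df.columns),
        values=body.to_numpy(dtype=float),
    )


def write_block(block: SensorBlock, path: str | Path) -> None:
    """Write a sensor block as CSV (full float precision round-trips)."""
    df = pd.DataFrame(block.values, index=list(block.sample_ids), columns=list(block.var_names))
    df.index.name = "id"
    df.to_csv(path, float_format="%.17g")


def load_labels(path: str | Path) -> LabelTable:
    """Read a label table with columns id, authenticity, species."""
    df = pd.read_csv(path, dtype=str)
    required = {"id", "authenticity", "species"}
    if not required.issubset(df.columns):
        raise DataError(f"label file must have columns {sorted(required)}")
    return LabelTable(
        sample_ids=tuple(df["id"]),
        authenticity=tuple(df["authenticity"]),
        species=tuple(df["species"]),
    )


def write_labels(labels: LabelTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": labels.sample_ids,
            "authenticity": labels.authenticity,
            "species": labels.species,
        }
    ).to_csv(path, index=False)


def assemble_dataset(
    blocks: Sequence[SensorBlock] | Mapping[str, SensorBlock],
    labels: LabelTable,
    task: str,
) -> FusionDataset:
    """Align blocks to the label table's sample order.

    Samples missing from any block are dropped (with a warning); the
    surviving samples appear in label order in every block.
    """
    if isinstance(blocks, Mapping):
        block_list = list(blocks.values())
    else:
        block_list = list(blocks)
    if not block_list:
        raise DataError("no blocks given")
    seen: dict[str, SensorBlock] = {}
    for block in block_list:
        if block.source in seen:
            raise DataError(f"duplicate block source {block.source}")
        seen[block.source] = block

    kept_ids = [
        sid
        for sid in labels.sample_ids
        if all(sid in set(b.sample_ids) for b in block_list)
    ]
    dropped = [sid for sid in labels.sample_ids if sid not in kept_ids]
    if dropped:
        msg = f"dropping {len(dropped)} sample(s) absent from some block: {dropped}"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)

    aligned = {
        source: seen[source].subset_samples(kept_ids)
        for source in SOURCES
        if source in seen
    }
    return FusionDataset(blocks=aligned, labels=labels.subset(kept_ids), task=task)
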