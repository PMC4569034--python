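"""Reciprocal-transplant trait records: types, CSV I/O and validation.

A reciprocal transplant grows each of two populations (A, B) in both its
own and the other population's environment, yielding four cells per trait:
``AinA`` (population A in its resident environment A), ``AinB``, ``BinB``
and ``BinA``.  One complete four-cell set for one trait in one study is a
:class:`TraitBlock` — the atomic unit of every downstream analysis.  Each
block decomposes into two :class:`PairedRecord` objects, one per
population, carrying that population's resident and nonresident cells.

Records are exchanged as long-format CSV: one row per
population x environment cell, with columns ``study_id, trait_name,
trait_category, population, environment, mean, dispersion_value,
dispersion_kind, n``.  The reader groups rows into blocks, normalizes
population/environment labels to {A, B} (first-listed population per
study is A), enforces the inclusion rules (n >= 10, a reported dispersion)
and reports incomplete blocks in a rejects table rather than guessing.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CELL_KEYS",
    "REQUIRED_COLUMNS",
    "DispersionKind",
    "TraitCategory",
    "CellMeasure",
    "TraitBlock",
    "PairedRecord",
    "ReadResult",
    "SchemaError",
    "ValidationError",
    "read_records",
    "write_records",
    "blocks_to_frame",
    "to_pairs",
    "normalize_dispersion",
]

#: The four cells of a complete block, in canonical order.
CELL_KEYS = ("AinA", "AinB", "BinB", "BinA")

REQUIRED_COLUMNS = (
    "study_id",
    "trait_name",
    "trait_category",
    "population",
    "environment",
    "mean",
    "dispersion_value",
    "dispersion_kind",
    "n",
)

#: Minimum individuals measured per cell for a study to be included.
MIN_SAMPLE_SIZE = 10


class SchemaError(ValueError):
    """The input table is missing required columns."""


class ValidationError(ValueError):
    """A row violates a hard inclusion rule (e.g. n < 10)."""


class DispersionKind(str, enum.Enum):
    """How a cell's intrapopulation variation was reported."""

    SE = "SE"
    SD = "SD"
    VAR = "VAR"


class TraitCategory(str, enum.Enum):
    """Three-way trait partition used throughout the reporting layer."""

    LIFE_HISTORY = "life_history"
    MORPHOLOGICAL = "morphological"
    PHYSIOLOGICAL = "physiological"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class CellMeasure:
    """Mean, dispersion and sample size for one population in one environment.

    ``dispersion_value`` is interpreted according to ``dispersion_kind``;
    the ``sd``/``se``/``var`` properties convert on the fly via
    SD = SE * sqrt(n) and VAR = SD**2.
    """

    mean: float
    dispersion_value: float
    dispersion_kind: DispersionKind
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValidationError(f"cell mean must be finite, got {self.mean!r}")
        if not (math.isfinite(self.dispersion_value) and self.dispersion_value >= 0):
            raise ValidationError(
                f"dispersion_value must be a nonnegative real, got {self.dispersion_value!r}"
            )
        object.__setattr__(self, "dispersion_kind", DispersionKind(self.dispersion_kind))
        if int(self.n) != self.n or self.n < MIN_SAMPLE_SIZE:
            raise ValidationError(
                f"sample size must be an integer >= {MIN_SAMPLE_SIZE}, got {self.n!r}"
            )
        object.__setattr__(self, "n", int(self.n))

    @property
    def sd(self) -> float:
        if self.dispersion_kind is DispersionKind.SD:
            return self.dispersion_value
        if self.dispersion_kind is DispersionKind.SE:
            return self.dispersion_value * math.sqrt(self.n)
        return math.sqrt(self.dispersion_value)

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.n)

    @property
    def var(self) -> float:
        return self.sd ** 2


def normalize_dispersion(cell: CellMeasure, target_kind: DispersionKind | str) -> CellMeasure:
    """Return ``cell`` with its dispersion re-expressed as ``target_kind``.

    Conversions pivot through the SD (SD = SE*sqrt(n), VAR = SD**2) and are
    invertible up to floating-point round-off.
    """
    target = DispersionKind(target_kind)
    if target is cell.dispersion_kind:
        return cell
    value = {DispersionKind.SD: cell.sd, DispersionKind.SE: cell.se, DispersionKind.VAR: cell.var}[
        target
    ]
    return replace(cell, dispersion_value=value, dispersion_kind=target)


@dataclass(frozen=True)
class TraitBlock:
    """The four cell measurements for one trait in one study."""

    study_id: str
    trait_name: str
    trait_category: TraitCategory
    cells: Mapping[str, CellMeasure]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trait_category", TraitCategory(self.trait_category))
        keys = set(self.cells)
        if keys != set(CELL_KEYS):
            raise ValidationError(
                f"block {self.block_id} must have exactly the cells {CELL_KEYS}, got {sorted(keys)}"
            )
        object.__setattr__(self, "cells", dict(self.cells))

    @property
    def block_id(self) -> str:
        return f"{self.study_id}/{self.trait_name}"

    def __getitem__(self, key: str) -> CellMeasure:
        return self.cells[key]

    @property
    def means(self) -> tuple[float, float, float, float]:
        """Cell means in canonical order (AinA, AinB, BinB, BinA)."""
        return tuple(self.cells[k].mean for k in CELL_KEYS)  # type: ignore[return-value]


@dataclass(frozen=True)
class PairedRecord:
    """One population's resident + nonresident cells within a block."""

    block_ref: str
    population: str  # "A" or "B"
    resident: CellMeasure
    nonresident: CellMeasure

    def __post_init__(self) -> None:
        if self.population not in ("A", "B"):
            raise ValidationError(f"population must be 'A' or 'B', got {self.population!r}")


def to_pairs(blocks: Iterable[TraitBlock]) -> list[PairedRecord]:
    """Split each block into its two paired records (population A, then B)."""
    pairs: list[PairedRecord] = []
    for block in blocks:
        pairs.append(
            PairedRecord(block.block_id, "A", block.cells["AinA"], block.cells["AinB"])
        )
        pairs.append(
            PairedRecord(block.block_id, "B", block.cells["BinB"], block.cells["BinA"])
        )
    return pairs


@dataclass
class ReadResult:
    """Blocks assembled by :func:`read_records` plus the rejects report."""

    blocks: list[TraitBlock]
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["study_id", "trait_name", "reason"])
    )

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)


def _normalize_labels(group: pd.DataFrame, study: str) -> pd.DataFrame | str:
    """Map a study's population/environment labels onto {A, B}.

    The first-listed population becomes "A"; environment labels must come
    from the same label set (a site is named after its home population).
    Returns the relabelled frame, or a rejection reason string.
    """
    pops = list(dict.fromkeys(group["population"].astype(str)))
    if len(pops) != 2:
        return f"expected exactly 2 populations per study, found {len(pops)}"
    mapping = {pops[0]: "A", pops[1]: "B"}
    envs = set(group["environment"].astype(str))
    if not envs <= set(mapping):
        unknown = sorted(envs - set(mapping))
        return f"environment labels {unknown} do not match the study's population labels"
    out = group.copy()
    out["population"] = out["population"].astype(str).map(mapping)
    out["environment"] = out["environment"].astype(str).map(mapping)
    return out


def read_records(path: str | Path, *, dialect: Mapping | None = None) -> ReadResult:
    """Read long-format CSV records and assemble them into complete blocks.

    Hard failures (missing columns, n < 10, bad dispersion) raise;
    incomplete or ambiguous blocks are excluded with a row in
    ``result.rejects`` and a warning.

    Parameters
    ----------
    path:
        CSV file with the columns in :data:`REQUIRED_COLUMNS`.
    dialect:
        Extra keyword arguments passed through to :func:`pandas.read_csv`.
    """
    kwargs = {"float_precision": "round_trip", **(dialect or {})}
    frame = pd.read_csv(path, **kwargs)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    blocks: list[TraitBlock] = []
    rejects: list[dict] = []

    for study, study_rows in frame.groupby("study_id", sort=False):
        relabelled = _normalize_labels(study_rows, str(study))
        if isinstance(relabelled, str):
            for trait in dict.fromkeys(study_rows["trait_name"]):
                rejects.append(
                    {"study_id": study, "trait_name": trait, "reason": relabelled}
                )
            continue
        for trait, rows in relabelled.groupby("trait_name", sort=False):
            keys = [f"{p}in{e}" for p, e in zip(rows["population"], rows["environment"])]
            if len(set(keys)) != len(keys):
                rejects.append(
                    {"study_id": study, "trait_name": trait, "reason": "duplicate cell"}
                )
                continue
            if set(keys) != set(CELL_KEYS):
                absent = sorted(set(CELL_KEYS) - set(keys))
                rejects.append(
                    {
                        "study_id": study,
                        "trait_name": trait,
                        "reason": f"incomplete block, missing {absent}",
                    }
                )
                continue
            cells = {}
            for key, (idx, row) in zip(keys, rows.iterrows()):
                try:
                    cells[key] = CellMeasure(
                        mean=float(row["mean"]),
                        dispersion_value=float(row["dispersion_value"]),
                        dispersion_kind=str(row["dispersion_kind"]).upper(),
                        n=int(row["n"]),
                    )
                except (ValueError, TypeError) as exc:
                    raise ValidationError(f"row {idx} ({study}/{trait}): {exc}") from exc
            category = str(rows["trait_category"].iloc[0])
            try:
                category = TraitCategory(category)
            except ValueError:
                category = TraitCategory.UNKNOWN
            blocks.append(TraitBlock(str(study), str(trait), category, cells))

    rejects_frame = pd.DataFrame(rejects, columns=["study_id", "trait_name", "reason"])
    if rejects:
        warnings.warn(
            f"excluded {len(rejects)} incomplete/ambiguous block(s); see the rejects report",
            stacklevel=2,
        )
    return ReadResult(blocks=blocks, rejects=rejects_frame)


def blocks_to_frame(blocks: Sequence[TraitBlock]) -> pd.DataFrame:
    """Flatten blocks back into the long CSV row format."""
    rows = []
    for block in blocks:
        for key in CELL_KEYS:
            cell = block.cells[key]
            rows.append(
                {
                    "study_id": block.study_id,
                    "trait_name": block.trait_name,
                    "trait_category": block.trait_category.value,
                    "population": key[0],
                    "environment": key[-1],
                    "mean": cell.mean,
                    "dispersion_value": cell.dispersion_value,
                    "dispersion_kind": cell.dispersion_kind.value,
                    "n": cell.n,
                }
            )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_records(blocks: Sequence[TraitBlock], path: str | Path) -> None:
    """Write blocks as long-format CSV readable by :func:`read_records`."""
    blocks_to_frame(blocks).to_csv(path, index=False)
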