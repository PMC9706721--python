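"""Core containers: ASV count tables, sample metadata, taxonomy.

ASV tables are exchanged as UTF-8 TSV with ASVs as rows and samples as
columns (the usual amplicon-table shape); stages that need sample x feature
matrices transpose internally. Bacteria and fungi are kept in separate
tables throughout, mirroring the per-kingdom reporting of every downstream
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ACTIVITIES = ("LA", "SA", "EA", "FA")
PARAMETERS = ("temperature", "moisture", "acidity")

METADATA_COLUMNS = (
    "sample_id", "mtd_type", "day", "replicate",
    "temperature", "moisture", "acidity", "LA", "SA", "EA", "FA",
)


class Kingdom(str, Enum):
    bacteria = "bacteria"
    fungi = "fungi"


class MtdType(str, Enum):
    """Treatment arm: DD = two-strain consortium, CD = single strain, PD = control."""

    DD = "DD"
    CD = "CD"
    PD = "PD"


class Phase(str, Enum):
    """Fermentation temperature phase: rising / stable-high / cooling."""

    RV = "RV"
    RS = "RS"
    C = "C"


def phase_of_day(day: int) -> Phase:
    """Phase is a pure function of day: RV for days 0-6, RS for 7-12, C from 13."""
    if day < 0:
        raise ValueError(f"negative fermentation day: {day}")
    if day <= 6:
        return Phase.RV
    if day <= 12:
        return Phase.RS
    return Phase.C


class FormatError(ValueError):
    """Structurally malformed input file (duplicates, missing columns)."""


@dataclass(frozen=True)
class CountTable:
    """Integer ASV x sample abundance matrix for one kingdom.

    Invariants: counts are non-negative integers, ids are unique, and every
    sample column has a positive total.
    """

    data: pd.DataFrame  # index: asv ids, columns: sample ids, dtype int64
    kingdom: Kingdom = Kingdom.bacteria

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise FormatError("duplicate ASV ids")
        if df.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        values = df.to_numpy()
        if values.size == 0:
            raise ValueError("empty count table")
        if not np.issubdtype(values.dtype, np.integer):
            if np.isnan(values.astype(float)).any():
                raise ValueError("NaN cell in count table")
            if not np.allclose(values, np.round(values.astype(float))):
                raise ValueError("non-integer cell in count table")
            object.__setattr__(self, "data", df.round().astype(np.int64))
            values = self.data.to_numpy()
        if (values < 0).any():
            raise ValueError("negative cell in count table")
        empty = self.data.sum(axis=0) == 0
        if empty.any():
            raise ValueError(
                f"empty sample column(s): {list(self.data.columns[empty])}"
            )

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_asvs(self, asv_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[list(asv_ids)], self.kingdom)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data[list(sample_ids)], self.kingdom)


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample design record plus fermentation parameters and activities.

    ``activities`` maps the four starter activities (LA liquefying, SA
    saccharifying, EA esterifying, FA fermenting) to non-negative values.
    """

    sample_id: str
    mtd_type: MtdType
    day: int
    replicate: int
    temperature: float
    moisture: float
    acidity: float
    activities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day < 0 for sample {self.sample_id}")
        if not 0.0 <= self.moisture <= 1.0:
            raise ValueError(f"moisture outside [0,1] for sample {self.sample_id}")
        if self.acidity < 0:
            raise ValueError(f"negative acidity for sample {self.sample_id}")
        for name, value in self.activities.items():
            if value < 0:
                raise ValueError(f"negative activity {name} for {self.sample_id}")

    @property
    def phase(self) -> Phase:
        return phase_of_day(self.day)


@dataclass(frozen=True)
class Taxonomy:
    """asv_id -> ranked lineage (kingdom..genus); missing ranks allowed."""

    lineages: Mapping[str, tuple[str, ...]]

    RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        return tuple(self.lineages.get(asv_id, ()))

    def genus(self, asv_id: str) -> str:
        lin = self.lineage(asv_id)
        return lin[5] if len(lin) > 5 and lin[5] else "unassigned"

    def covers(self, table: CountTable) -> bool:
        return all(a in self.lineages for a in table.asv_ids)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path, kingdom: Kingdom | str = Kingdom.bacteria) -> CountTable:
    """Read a TSV count table (first column ASV id, header row of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountTable(df, Kingdom(kingdom))


def write_count_table(table: CountTable, path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.data.rename_axis("asv_id").to_csv(fh, sep="\t")


def metadata_to_frame(meta: Sequence[SampleInfo]) -> pd.DataFrame:
    """Flatten SampleInfo records into a sample x column DataFrame (adds phase)."""
    rows = []
    for s in meta:
        row = {
            "sample_id": s.sample_id,
            "mtd_type": s.mtd_type.value,
            "day": s.day,
            "replicate": s.replicate,
            "phase": s.phase.value,
            "temperature": s.temperature,
            "moisture": s.moisture,
            "acidity": s.acidity,
        }
        for a in ACTIVITIES:
            row[a] = s.activities.get(a, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def frame_to_metadata(df: pd.DataFrame) -> list[SampleInfo]:
    meta = []
    for _, row in df.iterrows():
        try:
            mtd = MtdType(str(row["mtd_type"]))
        except ValueError:
            raise FormatError(f"unknown mtd_type: {row['mtd_type']!r}")
        meta.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                mtd_type=mtd,
                day=int(row["day"]),
                replicate=int(row["replicate"]),
                temperature=float(row["temperature"]),
                moisture=float(row["moisture"]),
                acidity=float(row["acidity"]),
                activities={a: float(row[a]) for a in ACTIVITIES if a in row and pd.notna(row[a])},
            )
        )
    return meta


def read_metadata(path) -> list[SampleInfo]:
    """Read sample metadata TSV; phase is derived from day, never read."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required column(s): {missing}")
    return frame_to_metadata(df)


def write_metadata(meta: Sequence[SampleInfo], path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        metadata_to_frame(meta).to_csv(fh, sep="\t", index=False)


def read_taxonomy(path) -> Taxonomy:
    """Read taxonomy TSV: asv_id <tab> semicolon-separated lineage."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    lineages = {}
    for _, row in df.iterrows():
        asv = str(row.iloc[0])
        if asv in lineages:
            raise FormatError(f"duplicate taxonomy entry: {asv}")
        raw = "" if pd.isna(row.iloc[1]) else str(row.iloc[1])
        lineages[asv] = tuple(part.strip() for part in raw.split(";")) if raw else ()
    return Taxonomy(lineages)


def write_taxonomy(tax: Taxonomy, path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("asv_id\tlineage\n")
        for asv in sorted(tax.lineages):
            fh.write(f"{asv}\t{';'.join(tax.lineages[asv])}\n")


def align(
    table: CountTable, meta: Sequence[SampleInfo]
) -> tuple[CountTable, list[SampleInfo]]:
    """Restrict table and metadata to their shared samples, in table order.

    Idempotent; dropped ids are logged. Raises if the intersection is empty.
    """
    meta_ids = {s.sample_id for s in meta}
    shared = [s for s in table.sample_ids if s in meta_ids]
    if not shared:
        raise ValueError("no shared sample ids between count table and metadata")
    dropped_t = sorted(set(table.sample_ids) - set(shared))
    dropped_m = sorted(meta_ids - set(shared))
    if dropped_t:
        log.info("align: dropped %d count-table sample(s): %s", len(dropped_t), dropped_t)
    if dropped_m:
        log.info("align: dropped %d metadata sample(s): %s", len(dropped_m), dropped_m)
    by_id = {s.sample_id: s for s in meta}
    return table.subset_samples(shared), [by_id[s] for s in shared]
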