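"""Domain types and CSV readers/writers for the merged feeding + milk + spectra dataset.

The modelling unit is one cow on one day.  Three per-cow-day sources (feeding
records, milk records, MIR spectra) are inner-joined on ``(cow_id, date)``;
diet composition comes from a fourth, diet-level table.  All files are plain
comma-separated UTF-8 with ISO-8601 dates; spectra are stored wide, one column
per wavenumber with the header holding the wavenumber in cm^-1 at two decimals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumGrid",
    "DietSpec",
    "Dataset",
    "JoinReport",
    "SchemaError",
    "DimensionError",
    "read_dataset",
    "write_dataset",
]


class SchemaError(ValueError):
    """An input file is missing a required column or has malformed keys."""


class DimensionError(ValueError):
    """A spectra row does not match the wavenumber grid length."""


@dataclasses.dataclass(frozen=True)
class SpectrumGrid:
    """An ordered wavenumber axis in cm^-1, strictly increasing and positive."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 1:
            raise ValueError("grid must be a non-empty 1-D vector")
        if np.any(wn <= 0):
            raise ValueError("wavenumbers must be positive")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectrumGrid):
            return NotImplemented
        return self.wavenumbers.shape == other.wavenumbers.shape and bool(
            np.all(self.wavenumbers == other.wavenumbers)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.wavenumbers.tobytes())

    def header(self) -> list[str]:
        """Column labels used in the wide spectra CSV (cm^-1, 2 decimals)."""
        return [f"{w:.2f}" for w in self.wavenumbers]


@dataclasses.dataclass(frozen=True)
class DietSpec:
    """Diet composition used for nitrogen-intake derivation.

    Parameters
    ----------
    diet_id : str
        Identifier referenced by per-cow-day records.
    dm_pct : float
        Dry matter content of the ration, % of fresh weight.
    cp_pct : float
        Crude protein, % of dry matter.  N intake = DMI * cp/100 / 6.25.
    cr_concentrate, cr_roughage : float
        Concentrate:roughage split on a dry-matter basis; must sum to 100.
    """

    diet_id: str
    dm_pct: float
    cp_pct: float
    cr_concentrate: float
    cr_roughage: float

    def __post_init__(self) -> None:
        if not 0 < self.dm_pct <= 100:
            raise ValueError(f"dm_pct out of (0, 100]: {self.dm_pct}")
        if not 0 < self.cp_pct <= 100:
            raise ValueError(f"cp_pct out of (0, 100]: {self.cp_pct}")
        if self.cr_concentrate <= 0 or self.cr_roughage <= 0:
            raise ValueError("concentrate and roughage parts must be positive")
        if abs(self.cr_concentrate + self.cr_roughage - 100.0) > 1e-9:
            raise ValueError("concentrate + roughage must sum to 100")


#: scalar per-cow-day columns of Dataset.table, in canonical order
RECORD_COLUMNS = [
    "cow_id",
    "date",
    "trial_id",
    "diet_id",
    "dmi_kg",
    "my_kg",
    "fat_pct",
    "protein_pct",
    "lactose_pct",
    "mun_mg_dl",
    "parity",
    "dim_d",
    "dip_d",
    "bcs",
]

_FEED_COLUMNS = ["cow_id", "date", "trial_id", "diet_id", "dmi_kg", "parity", "dim_d", "dip_d", "bcs"]
_MILK_COLUMNS = ["cow_id", "date", "my_kg", "fat_pct", "protein_pct", "lactose_pct", "mun_mg_dl"]
_DIET_COLUMNS = ["diet_id", "dm_pct", "cp_pct", "cr_concentrate", "cr_roughage"]


@dataclasses.dataclass
class JoinReport:
    """Bookkeeping from merging the three per-cow-day sources."""

    n_feed: int = 0
    n_milk: int = 0
    n_spectra: int = 0
    n_joined: int = 0

    @property
    def n_dropped(self) -> int:
        return max(self.n_feed, self.n_milk, self.n_spectra) - self.n_joined

    def __str__(self) -> str:
        return (
            f"join report: feed={self.n_feed} milk={self.n_milk} "
            f"spectra={self.n_spectra} -> joined={self.n_joined} "
            f"(dropped {self.n_dropped})"
        )


@dataclasses.dataclass
class Dataset:
    """Merged analysis dataset: one table row + one spectrum per cow-day.

    ``table`` holds the scalar fields (see :data:`RECORD_COLUMNS`, plus any
    derived trait columns appended later); ``spectra`` is the aligned
    ``(n_records, n_channels)`` absorbance matrix on ``grid``.
    """

    table: pd.DataFrame
    spectra: np.ndarray
    grid: SpectrumGrid
    diets: dict[str, DietSpec]

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (len(self.table), len(self.grid)):
            raise DimensionError(
                f"spectra shape {self.spectra.shape} does not match "
                f"{len(self.table)} records x {len(self.grid)} channels"
            )
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")
        missing = set(self.table["diet_id"]) - set(self.diets)
        if missing:
            raise SchemaError(f"records reference unknown diet_id(s): {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    def canonicalize(self) -> "Dataset":
        """Sort records by (cow_id, date), keeping spectra aligned."""
        order = self.table.sort_values(["cow_id", "date"], kind="mergesort").index.to_numpy()
        table = self.table.loc[order].reset_index(drop=True)
        return Dataset(table, self.spectra[order], self.grid, dict(self.diets))

    def subset(self, mask: np.ndarray) -> "Dataset":
        """Row subset by boolean mask or integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        table = self.table.iloc[idx].reset_index(drop=True)
        return Dataset(table, self.spectra[idx], self.grid, dict(self.diets))

    def equals(self, other: "Dataset") -> bool:
        a, b = self.canonicalize(), other.canonicalize()
        return (
            a.grid == b.grid
            and a.table.equals(b.table)
            and np.array_equal(a.spectra, b.spectra)
            and a.diets == b.diets
        )


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _reject_duplicates(df: pd.DataFrame, path: str | Path) -> None:
    dup = df.duplicated(subset=["cow_id", "date"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["cow_id", "date"]].tolist()
        raise SchemaError(f"{path}: duplicate (cow_id, date) key {key}")


def read_dataset(
    feed_path: str | Path,
    milk_path: str | Path,
    spectra_path: str | Path,
    diets_path: str | Path,
) -> tuple[Dataset, JoinReport]:
    """Read and inner-join the four CSV sources into a :class:`Dataset`.

    Rows missing from any of feed/milk/spectra are dropped and counted in the
    returned :class:`JoinReport`.  Duplicate ``(cow_id, date)`` keys within a
    single source are rejected rather than averaged.
    """
    # round_trip parser: shortest-repr floats read back bit-identically
    kw = dict(parse_dates=["date"], float_precision="round_trip")
    feed = pd.read_csv(feed_path, **kw)
    _require_columns(feed, _FEED_COLUMNS, feed_path)
    milk = pd.read_csv(milk_path, **kw)
    _require_columns(milk, _MILK_COLUMNS, milk_path)
    spec = pd.read_csv(spectra_path, **kw)
    _require_columns(spec, ["cow_id", "date"], spectra_path)
    diets_df = pd.read_csv(diets_path, float_precision="round_trip")
    _require_columns(diets_df, _DIET_COLUMNS, diets_path)

    for df, path in ((feed, feed_path), (milk, milk_path), (spec, spectra_path)):
        df["cow_id"] = df["cow_id"].astype(str)
        _reject_duplicates(df, path)

    wn_cols = [c for c in spec.columns if c not in ("cow_id", "date")]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SchemaError(f"{spectra_path}: non-numeric spectra column header") from exc
    grid = SpectrumGrid(wavenumbers)
    if spec[wn_cols].isna().any().any():
        row = int(spec[wn_cols].isna().any(axis=1).idxmax())
        raise DimensionError(
            f"{spectra_path}: row {row} has missing absorbance values "
            f"(expected {len(grid)} channels)"
        )

    report = JoinReport(n_feed=len(feed), n_milk=len(milk), n_spectra=len(spec))
    merged = feed.merge(milk, on=["cow_id", "date"], how="inner")
    merged = merged.merge(spec, on=["cow_id", "date"], how="inner")
    report.n_joined = len(merged)

    merged["diet_id"] = merged["diet_id"].astype(str)
    merged["trial_id"] = merged["trial_id"].astype(str)
    scalar_cols = [c for c in RECORD_COLUMNS if c in merged.columns]
    scalar_cols += [c for c in merged.columns if c not in wn_cols and c not in scalar_cols]
    table = merged[scalar_cols].reset_index(drop=True)
    spectra = merged[wn_cols].to_numpy(dtype=float)

    diets = {
        str(r.diet_id): DietSpec(
            str(r.diet_id), r.dm_pct, r.cp_pct, r.cr_concentrate, r.cr_roughage
        )
        for r in diets_df.itertuples()
    }
    ds = Dataset(table, spectra, grid, diets).canonicalize()
    return ds, report


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four-CSV layout; returns a file manifest.

    Floats are written with shortest round-trip repr so that
    ``read_dataset(*write_dataset(ds))`` reproduces ``ds`` bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = ds.canonicalize()

    extra = [c for c in ds.table.columns if c not in RECORD_COLUMNS]
    feed_cols = _FEED_COLUMNS + [c for c in extra if c not in _MILK_COLUMNS]
    manifest = {
        "feed": out / "feed.csv",
        "milk": out / "milk.csv",
        "spectra": out / "spectra.csv",
        "diets": out / "diets.csv",
    }
    date_str = ds.table["date"].dt.strftime("%Y-%m-%d") if len(ds.table) else ds.table["date"]

    feed = ds.table[[c for c in feed_cols if c in ds.table.columns]].copy()
    feed["date"] = date_str
    feed.to_csv(manifest["feed"], index=False)

    milk = ds.table[_MILK_COLUMNS].copy()
    milk["date"] = date_str
    milk.to_csv(manifest["milk"], index=False)

    spec = pd.DataFrame(ds.spectra, columns=ds.grid.header())
    spec.insert(0, "date", date_str.to_numpy() if len(ds.table) else [])
    spec.insert(0, "cow_id", ds.table["cow_id"].to_numpy())
    spec.to_csv(manifest["spectra"], index=False)

    diets = pd.DataFrame(
        [dataclasses.asdict(d) for d in ds.diets.values()], columns=_DIET_COLUMNS
    )
    diets.to_csv(manifest["diets"], index=False)
    return manifest
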