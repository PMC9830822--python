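"""Nitrogen-balance trait derivation, engineered covariates, and record QC.

Traits follow the standard nitrogen-balance bookkeeping for lactating cows:

* N intake (kg N/d)  = DMI (kg DM/d) x CP% of DM / 100 / 6.25
* N output (kg N/d)  = milk yield (kg/d) x protein% / 100 / 6.38
* NUE (%)            = 100 x N output / N intake
* NL (kg N/d)        = N intake - N output

Body-weight change is deliberately ignored: over mid/late lactation the N
flux into or out of body reserves is small relative to milk N, so milk output
over feed intake is the whole balance considered here.  DMI enters through
its 3-day moving average (DMI_a) to damp day-to-day feeder noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = [
    "CP_TO_N",
    "MILK_PROTEIN_TO_N",
    "QC_BOUNDS",
    "nitrogen_intake",
    "nitrogen_output",
    "moving_average_dmi",
    "derive_traits",
    "engineer_covariates",
    "qc_filter",
    "QCReport",
]

#: crude protein to nitrogen divisor (feed side)
CP_TO_N = 6.25
#: milk true+casein protein to nitrogen divisor (milk side)
MILK_PROTEIN_TO_N = 6.38

#: inclusive retention bounds applied per record; None means unbounded
QC_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "my_kg": (5.0, 80.0),
    "protein_pct": (2.5, 5.0),
    "fat_pct": (3.0, 5.0),
    "mun_mg_dl": (5.0, 20.0),
    "dmi_a_kg": (5.0, None),
}


def nitrogen_intake(dmi_kg, cp_pct):
    """Daily nitrogen intake (kg N/d) from dry matter intake and diet CP%."""
    dmi = np.asarray(dmi_kg, dtype=float)
    cp = np.asarray(cp_pct, dtype=float)
    if np.any(dmi < 0):
        raise ValueError("dmi_kg must be non-negative")
    if np.any((cp <= 0) | (cp > 100)):
        raise ValueError("cp_pct must lie in (0, 100]")
    out = dmi * (cp / 100.0) / CP_TO_N
    return float(out) if out.ndim == 0 else out


def nitrogen_output(my_kg, protein_pct):
    """Daily milk nitrogen output (kg N/d) from milk yield and protein%."""
    my = np.asarray(my_kg, dtype=float)
    prot = np.asarray(protein_pct, dtype=float)
    if np.any(my < 0) or np.any(prot < 0):
        raise ValueError("my_kg and protein_pct must be non-negative")
    out = my * (prot / 100.0) / MILK_PROTEIN_TO_N
    return float(out) if out.ndim == 0 else out


def moving_average_dmi(dates: pd.Series, dmi: pd.Series) -> pd.Series:
    """Trailing 3-calendar-day moving average of DMI for one cow.

    The window for day *d* is {d-2, d-1, d}; the mean is taken over the days
    actually present, so a series with gaps still averages >= 1 value.
    Input must be sorted by date with unique dates.
    """
    if len(dates) == 0:
        return pd.Series(dtype=float)
    d = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    if d.is_monotonic_increasing is False or d.duplicated().any():
        raise ValueError("dates must be sorted and unique within a cow")
    v = pd.Series(np.asarray(dmi, dtype=float))
    day = (d - d.iloc[0]).dt.days.to_numpy()
    out = np.empty(len(v))
    for i in range(len(v)):
        in_window = (day >= day[i] - 2) & (day <= day[i])
        out[i] = v[in_window].mean()
    return pd.Series(out)


def derive_traits(ds: Dataset) -> Dataset:
    """Append dmi_a_kg, n_intake_kg, n_output_kg, nue_pct and nl_kg columns.

    DMI_a is computed per cow over its (sorted) date series; N intake uses the
    record's resolved diet CP% with DMI_a as the intake measure.
    """
    ds = ds.canonicalize()
    t = ds.table.copy()
    dmi_a = np.empty(len(t))
    for _, idx in t.groupby("cow_id", sort=False).groups.items():
        sub = t.loc[idx]
        dmi_a[t.index.get_indexer(idx)] = moving_average_dmi(sub["date"], sub["dmi_kg"]).to_numpy()
    t["dmi_a_kg"] = dmi_a
    cp = t["diet_id"].map(lambda d: ds.diets[d].cp_pct).to_numpy(dtype=float)
    t["n_intake_kg"] = nitrogen_intake(t["dmi_a_kg"].to_numpy(), cp)
    t["n_output_kg"] = nitrogen_output(t["my_kg"].to_numpy(), t["protein_pct"].to_numpy())
    if np.any(t["n_intake_kg"].to_numpy() == 0):
        raise ZeroDivisionError("zero N intake: NUE undefined")
    t["nue_pct"] = 100.0 * t["n_output_kg"] / t["n_intake_kg"]
    t["nl_kg"] = t["n_intake_kg"] - t["n_output_kg"]
    return Dataset(t, ds.spectra, ds.grid, dict(ds.diets))


def engineer_covariates(ds: Dataset) -> Dataset:
    """Append parity_group (primiparous iff parity == 1) and dim_g columns.

    DIM is binned every 5 days anchored at day 1, so bin 0 covers days 1-5:
    dim_g = floor((dim - 1) / 5).
    """
    t = ds.table.copy()
    parity = t["parity"].to_numpy()
    if np.any(parity < 1):
        raise ValueError("parity must be >= 1")
    dim = t["dim_d"].to_numpy()
    if np.any(dim <= 0):
        raise ValueError("dim_d must be positive")
    t["parity_group"] = np.where(parity == 1, "primiparous", "multiparous")
    t["dim_g"] = ((dim - 1) // 5).astype(int)
    return Dataset(t, ds.spectra, ds.grid, dict(ds.diets))


@dataclasses.dataclass
class QCReport:
    """Per-rule rejection counts; a record violating k rules counts in each."""

    n_in: int
    n_retained: int
    rejections: dict[str, int]

    def __str__(self) -> str:
        lines = [f"QC: {self.n_in} records in, {self.n_retained} retained"]
        lines += [f"  {rule}: {n} rejected" for rule, n in self.rejections.items()]
        return "\n".join(lines)


def qc_filter(ds: Dataset) -> tuple[Dataset, QCReport]:
    """Drop records outside the inclusive QC bounds (:data:`QC_BOUNDS`).

    Requires derived ``dmi_a_kg`` (run :func:`derive_traits` first).
    Idempotent: filtering a filtered dataset changes nothing.
    """
    t = ds.table
    keep = np.ones(len(t), dtype=bool)
    rejections: dict[str, int] = {}
    for col, (lo, hi) in QC_BOUNDS.items():
        x = t[col].to_numpy(dtype=float)
        bad = np.zeros(len(t), dtype=bool)
        if lo is not None:
            bad |= x < lo
        if hi is not None:
            bad |= x > hi
        rejections[col] = int(bad.sum())
        keep &= ~bad
    report = QCReport(n_in=len(t), n_retained=int(keep.sum()), rejections=rejections)
    return ds.subset(keep), report
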