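"""Avalanche accident table ingest and empirical distributions.

The Swiss avalanche registry snapshot this package consumes is a flat CSV
with one row per fully buried subject: an opaque avalanche identifier, the
burial depth in centimetres, and the area of the avalanche deposit in
square metres.  Either measurement may be blank; rows with neither are
useless for the simulations and are dropped (with a warning) but counted,
because real snapshots are known to contain such rows.

All downstream computation is in metres and minutes; depth is converted
from centimetres on ingest and never afterwards.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AvalancheRecord",
    "AvalancheTable",
    "EmpiricalDistribution",
    "DataSummary",
    "read_avalanche_table",
    "summarize",
    "to_distribution",
]

logger = logging.getLogger(__name__)

#: substrings used to locate the three columns in a header, case-insensitive
_COLUMN_KEYS = {"id": "id", "depth": "depth", "area": "area"}


@dataclass(frozen=True)
class AvalancheRecord:
    """One fully buried subject: burial depth [m] and/or deposit area [m²]."""

    avalanche_id: str
    burial_depth_m: float | None = None
    deposit_area_m2: float | None = None

    def __post_init__(self) -> None:
        if self.burial_depth_m is not None and not self.burial_depth_m > 0:
            raise ValueError(f"burial_depth_m must be > 0, got {self.burial_depth_m}")
        if self.deposit_area_m2 is not None and not self.deposit_area_m2 > 0:
            raise ValueError(f"deposit_area_m2 must be > 0, got {self.deposit_area_m2}")
        if self.burial_depth_m is None and self.deposit_area_m2 is None:
            raise ValueError("a record needs at least one of depth or area")


@dataclass(frozen=True)
class AvalancheTable(Sequence):
    """Parsed table: the kept records plus ingest bookkeeping.

    ``len(table)`` is the number of usable records; ``n_rows_read`` counts
    every data row in the file, including rows rejected because both
    measurement fields were blank or invalid.
    """

    records: tuple[AvalancheRecord, ...]
    n_rows_read: int
    n_rejected: int
    source: str | None = None

    def __getitem__(self, i):  # Sequence protocol
        return self.records[i]

    def __len__(self) -> int:
        return len(self.records)

    def summarize(self) -> "DataSummary":
        return summarize(self.records)

    def depth_distribution(self) -> "EmpiricalDistribution":
        return to_distribution(self.records, "burial_depth")

    def area_distribution(self) -> "EmpiricalDistribution":
        return to_distribution(self.records, "deposit_area")


class EmpiricalDistribution:
    """An ordered multiset of positive values resampled uniformly.

    This is the Monte Carlo engines' source of burial depths (and deposit
    areas): ``sample`` draws stored values with equal probability 1/n, so
    the simulated population is exactly the recorded one.  Quantiles use
    linear interpolation between order statistics (numpy's default,
    the common "type 7" convention).
    """

    def __init__(self, values: Iterable[float], unit: str = "") -> None:
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValueError("empirical distribution needs at least one value")
        if not np.all(arr > 0):
            raise ValueError("all values must be > 0")
        self.values = arr
        self.unit = unit

    @property
    def n(self) -> int:
        return int(self.values.size)

    def quantile(self, q) -> float | np.ndarray:
        return np.quantile(self.values, q)

    def tail_fraction(self, x: float) -> float:
        """Fraction of stored values strictly greater than ``x``."""
        return float(np.mean(self.values > x))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Uniform draw(s) with replacement; same seed, same sequence."""
        idx = rng.integers(0, self.values.size, size=size)
        return self.values[idx]

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        u = f" {self.unit}" if self.unit else ""
        return (
            f"EmpiricalDistribution(n={self.n}, median={np.median(self.values):.3g}{u})"
        )


@dataclass(frozen=True)
class DataSummary:
    """Counts and quartiles of the present fields of a record collection."""

    n_total: int
    n_depth: int
    n_area: int
    n_both: int
    quartiles_depth_m: tuple[float, float, float] | None
    quartiles_area_m2: tuple[float, float, float] | None
    n_rejected: int = 0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_depth": self.n_depth,
            "n_area": self.n_area,
            "n_both": self.n_both,
            "n_rejected": self.n_rejected,
            "quartiles_depth_m": list(self.quartiles_depth_m)
            if self.quartiles_depth_m
            else None,
            "quartiles_area_m2": list(self.quartiles_area_m2)
            if self.quartiles_area_m2
            else None,
        }

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        rows = {k: v for k, v in d.items() if not isinstance(v, list)}
        for key in ("quartiles_depth_m", "quartiles_area_m2"):
            if d[key] is not None:
                q1, q2, q3 = d[key]
                rows[f"{key}_q1"], rows[f"{key}_q2"], rows[f"{key}_q3"] = q1, q2, q3
        return pd.DataFrame([rows])


def _match_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map the roles id/depth/area onto actual header names."""
    out: dict[str, str] = {}
    lowered = {c: str(c).strip().lower() for c in columns}
    for role, key in _COLUMN_KEYS.items():
        hits = [c for c, low in lowered.items() if key in low]
        if not hits:
            raise ValueError(
                f"header does not contain a column for '{role}' "
                f"(looked for '{key}' in {list(columns)})"
            )
        out[role] = hits[0]
    return out


def read_avalanche_table(path, delimiter: str = ",") -> AvalancheTable:
    """Read an avalanche snapshot CSV into records.

    The header must name an id, a depth and an area column (matched
    case-insensitively by substring).  Depth cells are centimetres and are
    converted to metres; blank, non-numeric or non-positive measurement
    cells become absent fields.  Rows where both measurements end up absent
    are rejected with a warning and counted in ``n_rejected``.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    cols = _match_columns(df.columns)

    depth_cm = pd.to_numeric(df[cols["depth"]], errors="coerce")
    area = pd.to_numeric(df[cols["area"]], errors="coerce")
    depth_cm = depth_cm.where(depth_cm > 0)
    area = area.where(area > 0)

    records: list[AvalancheRecord] = []
    n_rejected = 0
    for i in range(len(df)):
        d = depth_cm.iloc[i]
        a = area.iloc[i]
        if pd.isna(d) and pd.isna(a):
            n_rejected += 1
            logger.warning(
                "row %d (id=%r): no usable depth or area, dropped",
                i + 2,  # header is line 1
                df[cols["id"]].iloc[i],
            )
            continue
        records.append(
            AvalancheRecord(
                avalanche_id=str(df[cols["id"]].iloc[i]).strip(),
                burial_depth_m=None if pd.isna(d) else float(d) / 100.0,
                deposit_area_m2=None if pd.isna(a) else float(a),
            )
        )
    return AvalancheTable(
        records=tuple(records),
        n_rows_read=len(df),
        n_rejected=n_rejected,
        source=str(path),
    )


def _quartiles(values: list[float]) -> tuple[float, float, float] | None:
    if not values:
        return None
    q = np.quantile(np.asarray(values, dtype=float), [0.25, 0.5, 0.75])
    return (float(q[0]), float(q[1]), float(q[2]))


def summarize(records: Iterable[AvalancheRecord], n_rejected: int = 0) -> DataSummary:
    """Counts of present fields and their quartiles (type-7 quantiles)."""
    recs = list(records)
    if not recs:
        raise ValueError("cannot summarize an empty record collection")
    depths = [r.burial_depth_m for r in recs if r.burial_depth_m is not None]
    areas = [r.deposit_area_m2 for r in recs if r.deposit_area_m2 is not None]
    n_both = sum(
        1
        for r in recs
        if r.burial_depth_m is not None and r.deposit_area_m2 is not None
    )
    return DataSummary(
        n_total=len(recs),
        n_depth=len(depths),
        n_area=len(areas),
        n_both=n_both,
        quartiles_depth_m=_quartiles(depths),
        quartiles_area_m2=_quartiles(areas),
        n_rejected=n_rejected,
    )


def to_distribution(
    records: Iterable[AvalancheRecord], field_name: str
) -> EmpiricalDistribution:
    """Collect the present values of one field, order preserved.

    ``field_name`` is ``"burial_depth"`` (metres) or ``"deposit_area"`` (m²).
    """
    if field_name == "burial_depth":
        vals = [r.burial_depth_m for r in records if r.burial_depth_m is not None]
        unit = "m"
    elif field_name == "deposit_area":
        vals = [r.deposit_area_m2 for r in records if r.deposit_area_m2 is not None]
        unit = "m^2"
    else:
        raise ValueError(
            f"field must be 'burial_depth' or 'deposit_area', got {field_name!r}"
        )
    if not vals:
        raise ValueError(f"no record carries the field {field_name!r}")
    return EmpiricalDistribution(vals, unit=unit)
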