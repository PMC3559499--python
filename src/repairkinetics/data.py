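"""Measurement tables: replicate band quantitations per condition and time.

A measurement table is tidy/long: one row per (condition, time, replicate,
observable) with the background-subtracted fraction of total hybridisation
signal in that band.  The two observables are ``linear_total`` (the linear
band, L + LSSB, which co-migrate) and ``supercoiled`` (the S band).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .kinetics import OBSERVABLE_NAMES

__all__ = ["MeasurementTable", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("condition", "time_h", "replicate", "observable", "value")

# small overshoot above 1 tolerated: noisy gel signals can exceed the total
_VALUE_MAX = 1.1


@dataclass(frozen=True)
class MeasurementTable:
    """Validated table of replicate observable values.

    Construct via :meth:`from_dataframe` or :meth:`from_csv`; the underlying
    :class:`pandas.DataFrame` is available as ``.frame``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", _validate_frame(self.frame))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MeasurementTable":
        return cls(frame=df)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "MeasurementTable":
        return cls(frame=pd.DataFrame.from_records(list(records)))

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ValidationError(f"{path}: empty measurement file") from exc
        return cls(frame=df)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.frame["condition"]))

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_h"].unique())

    def replicate_values(self, condition: str, time_h: float, observable: str) -> np.ndarray:
        """All replicate values at one design cell, in replicate order."""
        f = self.frame
        mask = (
            (f["condition"] == condition)
            & np.isclose(f["time_h"], time_h)
            & (f["observable"] == observable)
        )
        sel = f.loc[mask].sort_values("replicate")
        if sel.empty:
            raise ValidationError(
                f"no measurements for condition={condition!r}, "
                f"time_h={time_h}, observable={observable!r}"
            )
        return sel["value"].to_numpy(dtype=float)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(df, pd.DataFrame):
        raise ValidationError("measurements must be a pandas DataFrame")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValidationError("measurement table has no rows")

    df = df.reset_index(drop=True).copy()
    for col, kind in (("time_h", float), ("value", float), ("replicate", int)):
        try:
            df[col] = df[col].astype(kind)
        except (TypeError, ValueError):
            bad = _first_bad_numeric(df[col])
            raise ValidationError(
                f"row {bad + 1}: column {col!r} is not numeric "
                f"(value {df[col].iloc[bad]!r})"
            ) from None

    for i, row in df.iterrows():
        rownum = int(i) + 1  # 1-based, header excluded
        if row["observable"] not in OBSERVABLE_NAMES:
            raise ValidationError(
                f"row {rownum}: unknown observable {row['observable']!r} "
                f"(expected one of {OBSERVABLE_NAMES}); nicked circles are not "
                "quantitated on the gel"
            )
        if row["time_h"] < 0:
            raise ValidationError(f"row {rownum}: negative time {row['time_h']!r}")
        if row["replicate"] < 1:
            raise ValidationError(f"row {rownum}: replicate must be >= 1")
        if not (0.0 <= row["value"] <= _VALUE_MAX):
            raise ValidationError(
                f"row {rownum}: value {row['value']!r} outside [0, {_VALUE_MAX}]"
            )
    return df


def _first_bad_numeric(col: pd.Series) -> int:
    for i, v in enumerate(col):
        try:
            float(v)
        except (TypeError, ValueError):
            return i
    return 0
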