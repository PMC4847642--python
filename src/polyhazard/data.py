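"""Right-censored survival datasets.

A :class:`SurvivalData` wraps a pandas DataFrame with columns

- ``time``  : positive survival/censoring time in years
- ``event`` : 1 = death observed, 0 = right-censored
- ``cause`` : (optional) 1-based cause label, present only on events
- ``group`` : group label (e.g. "population", "study")
- ``age``, ``sex`` : (optional) matching covariates

Cause labels identify the latent hazard component: cause ``k`` maps to
component index ``k - 1``.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = ["SurvivalData"]

_REQUIRED = ("time", "event")
_OPTIONAL = ("cause", "group", "age", "sex")


class SurvivalData:
    """Validated container for right-censored survival records."""

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        frame = frame.reset_index(drop=True).copy()
        if validate:
            _validate(frame)
        self.frame = frame

    # -- constructors -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        time,
        event,
        cause=None,
        group: str | Iterable[str] = "study",
        age=None,
        sex=None,
    ) -> "SurvivalData":
        n = len(np.asarray(time))
        cols = {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
        }
        if cause is not None:
            cols["cause"] = pd.array(cause, dtype="Int64")
        cols["group"] = (
            np.repeat(group, n) if isinstance(group, str) else np.asarray(group)
        )
        if age is not None:
            cols["age"] = np.asarray(age)
        if sex is not None:
            cols["sex"] = np.asarray(sex)
        return cls(pd.DataFrame(cols))

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    @property
    def cause(self) -> Optional[np.ndarray]:
        if "cause" not in self.frame.columns:
            return None
        return self.frame["cause"].to_numpy(dtype=float)  # NaN on censored rows

    @property
    def groups(self) -> np.ndarray:
        if "group" not in self.frame.columns:
            return np.repeat("study", len(self))
        return self.frame["group"].to_numpy()

    @property
    def cause_labelled(self) -> bool:
        """True if every event carries a cause label."""
        if "cause" not in self.frame.columns or len(self) == 0:
            return False
        ev = self.frame["event"] == 1
        return bool(self.frame.loc[ev, "cause"].notna().all())

    def subset(self, group: str) -> "SurvivalData":
        sub = self.frame[self.frame["group"] == group]
        return SurvivalData(sub, validate=False)

    def group_labels(self):
        if "group" not in self.frame.columns:
            return ["study"]
        return list(pd.unique(self.frame["group"]))

    def concat(self, other: "SurvivalData") -> "SurvivalData":
        return SurvivalData(
            pd.concat([self.frame, other.frame], ignore_index=True), validate=False
        )

    def __repr__(self) -> str:
        groups = ", ".join(map(str, self.group_labels()))
        return (
            f"SurvivalData(n={len(self)}, events={int(self.event.sum())}, "
            f"cause_labelled={self.cause_labelled}, groups=[{groups}])"
        )


def _validate(frame: pd.DataFrame) -> None:
    for col in _REQUIRED:
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")
    bad = frame.index[~(frame["time"] > 0) | ~np.isfinite(frame["time"])]
    if len(bad):
        raise ValueError(f"times must be positive and finite; bad rows: {list(bad)}")
    bad = frame.index[~frame["event"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"event must be 0 or 1; bad rows: {list(bad)}")
    if "cause" in frame.columns:
        cens = frame["event"] == 0
        bad = frame.index[cens & frame["cause"].notna()]
        if len(bad):
            raise ValueError(
                f"cause label present on censored rows: {list(bad)}"
            )
        ev = frame["cause"].notna()
        vals = frame.loc[ev, "cause"]
        if len(vals) and ((vals < 1) | (vals != vals.astype(int))).any():
            raise ValueError("cause labels must be positive integers (1-based)")
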