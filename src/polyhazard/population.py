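"""Matched general-population controls from life tables and cause fractions.

Long-term population survival enters the joint model as individual-level
records sampled from annual life tables: for each study patient, a
number of controls of the same entry age and sex walk the life table
year by year, dying in a given year with that year's annual death
probability q(age, sex).  Deaths get a Uniform(0,1)-year within-year
offset (the likelihoods need continuous, untied times) and a cause label
(cause of interest vs other) drawn with the age-group-at-death fraction
from a cause-of-death table.  The terminal age forces q = 1, so controls
are followed to death and the resulting dataset has no censoring.

Also provides the cause-reclassification sensitivity transform (randomly
relabel a fraction of cause-1 deaths as cause 2) and small synthetic
Gompertz-Makeham tables for tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import SurvivalData

__all__ = [
    "LifeTable",
    "CauseFractionTable",
    "sample_controls",
    "build_matched_population",
    "reclassify_causes",
    "synthetic_life_table",
    "synthetic_cause_fractions",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(age, sex).

    ``table`` needs columns ``age`` (whole years), ``sex`` and ``qx`` in
    [0, 1]; every age from the per-sex minimum up to ``max_age`` must be
    present.  At ``max_age`` the probability is treated as 1 regardless
    of the stored value.
    """

    table: pd.DataFrame
    max_age: int

    def __post_init__(self):
        t = self.table
        for col in ("age", "sex", "qx"):
            if col not in t.columns:
                raise ValueError(f"life table missing column {col!r}")
        if ((t["qx"] < 0) | (t["qx"] > 1)).any():
            raise ValueError("life-table qx values must lie in [0, 1]")
        for sex, sub in t.groupby("sex"):
            ages = np.sort(sub["age"].to_numpy())
            expect = np.arange(ages.min(), self.max_age + 1)
            if len(ages) != len(expect) or (ages != expect).any():
                raise ValueError(
                    f"life table for sex {sex!r} must cover every age up to "
                    f"max_age={self.max_age}"
                )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, max_age: Optional[int] = None):
        max_age = int(frame["age"].max()) if max_age is None else int(max_age)
        return cls(frame.reset_index(drop=True), max_age)

    def q_vector(self, start_age: int, sex: str) -> np.ndarray:
        """q for ages start_age..max_age; the final entry is forced to 1."""
        sub = self.table[self.table["sex"] == sex]
        if len(sub) == 0:
            raise ValueError(f"no life-table entries for sex {sex!r}")
        sub = sub.set_index("age")["qx"]
        ages = np.arange(start_age, self.max_age + 1)
        try:
            q = sub.loc[ages].to_numpy(dtype=float)
        except KeyError:
            raise ValueError(
                f"life table does not cover ages {start_age}..{self.max_age} "
                f"for sex {sex!r}"
            ) from None
        q[-1] = 1.0
        return q


@dataclass(frozen=True)
class CauseFractionTable:
    """Fraction of deaths from the cause of interest by age group and sex.

    ``table`` needs columns ``age_start``, ``age_end`` (inclusive bounds
    of the group), ``sex`` and ``fraction`` in [0, 1].  Lookup uses the
    age at death; ages beyond the last group use the last group's value.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in ("age_start", "age_end", "sex", "fraction"):
            if col not in t.columns:
                raise ValueError(f"cause-fraction table missing column {col!r}")
        if ((t["fraction"] < 0) | (t["fraction"] > 1)).any():
            raise ValueError("cause fractions must lie in [0, 1]")

    def fraction(self, age: float, sex: str) -> float:
        sub = self.table[self.table["sex"] == sex].sort_values("age_start")
        if len(sub) == 0:
            raise ValueError(f"no cause-fraction entries for sex {sex!r}")
        hit = sub[(sub["age_start"] <= age) & (age <= sub["age_end"])]
        if len(hit):
            return float(hit["fraction"].iloc[0])
        if age > sub["age_end"].max():
            return float(sub["fraction"].iloc[-1])
        raise ValueError(f"age {age} not covered by the cause-fraction table")


def sample_controls(
    life_table: LifeTable,
    cause_fractions: CauseFractionTable,
    age: int,
    sex: str,
    n_controls: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SurvivalData:
    """Simulate matched controls' death times and causes from entry age.

    Each control's survival status is sampled year by year with the
    period life table's q(age + elapsed, sex); death in year ``y`` gives
    time ``y + U(0,1)`` years since entry.  Every control dies by
    ``max_age``, so the output has no censored records.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    q = life_table.q_vector(int(age), sex)
    n_years = len(q)
    u = rng.uniform(size=(n_controls, n_years))
    died = u < q[None, :]
    year = died.argmax(axis=1)  # first year with a death draw; q[-1]=1 guarantees one
    time = year + rng.uniform(size=n_controls)
    age_at_death = int(age) + year
    frac = np.array(
        [cause_fractions.fraction(a, sex) for a in age_at_death], dtype=float
    )
    cause = np.where(rng.uniform(size=n_controls) < frac, 1, 2)
    return SurvivalData.from_arrays(
        time=time,
        event=np.ones(n_controls, dtype=int),
        cause=cause,
        group="population",
        age=np.full(n_controls, int(age)),
        sex=np.full(n_controls, sex),
    )


def build_matched_population(
    study_data: SurvivalData,
    life_table: LifeTable,
    cause_fractions: CauseFractionTable,
    controls_per_patient: int = 20,
    seed: Optional[int] = None,
) -> SurvivalData:
    """Age/sex-matched control dataset: ``controls_per_patient`` controls
    sampled per study patient; output size is that multiple of the study
    size."""
    frame = study_data.frame
    missing = frame.index[
        frame.get("age", pd.Series(np.nan, index=frame.index)).isna()
        | frame.get("sex", pd.Series(np.nan, index=frame.index)).isna()
    ]
    if "age" not in frame.columns or "sex" not in frame.columns or len(missing):
        raise ValueError(
            "study records need age and sex for matching; offending rows: "
            f"{list(missing) if len(missing) else 'all (columns absent)'}"
        )
    rng = np.random.default_rng(seed)
    parts = []
    for _, row in frame.iterrows():
        parts.append(
            sample_controls(
                life_table,
                cause_fractions,
                int(row["age"]),
                row["sex"],
                controls_per_patient,
                rng=rng,
            ).frame
        )
    if not parts:
        return SurvivalData.from_arrays(
            np.empty(0), np.empty(0, dtype=int), cause=pd.array([], dtype="Int64"),
            group="population",
        )
    return SurvivalData(pd.concat(parts, ignore_index=True), validate=False)


def reclassify_causes(
    dataset: SurvivalData, fraction: float, seed: Optional[int] = None
) -> SurvivalData:
    """Randomly relabel cause-1 deaths as cause 2 with the given probability.

    Times and event indicators are untouched; only cause labels change.
    Used as a sensitivity analysis for misclassified causes of death.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if not dataset.cause_labelled:
        raise ValueError("dataset must be cause-labelled")
    rng = np.random.default_rng(seed)
    frame = dataset.frame.copy()
    is_c1 = (frame["event"] == 1) & (frame["cause"] == 1)
    flip = rng.uniform(size=len(frame)) < fraction
    frame.loc[is_c1 & flip, "cause"] = 2
    return SurvivalData(frame, validate=False)


def synthetic_life_table(max_age: int = 100) -> LifeTable:
    """Synthetic Gompertz-Makeham period life table (not official data).

    ``q(age) = 1 - exp(-(a + b * exp(c * age)))`` with a small constant
    background and exponentially increasing senescent mortality; female
    rates are shifted about three years younger in effect.  Intended for
    tests and examples where a real national life table is unavailable.
    """
    ages = np.arange(0, max_age + 1)
    rows = []
    for sex, shift in (("M", 0.0), ("F", 3.0)):
        haz = 5e-4 + 3.5e-5 * np.exp(0.092 * np.clip(ages - shift, 0, None))
        q = 1.0 - np.exp(-haz)
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "qx": np.clip(q, 0, 1)}))
    return LifeTable(pd.concat(rows, ignore_index=True), max_age=max_age)


def synthetic_cause_fractions() -> CauseFractionTable:
    """Synthetic cause-of-interest death fractions by 5-year age group.

    Roughly constant around 0.25 for males and rising with age for
    females, mimicking the qualitative pattern of arrhythmia-related
    death fractions; for tests and examples only.
    """
    starts = np.arange(0, 100, 5)
    rows = []
    for sex in ("M", "F"):
        for s in starts:
            if sex == "M":
                frac = 0.25
            else:
                frac = float(np.clip(0.10 + 0.004 * max(s - 40, 0), 0.0, 0.45))
            rows.append(
                {"age_start": s, "age_end": s + 4, "sex": sex, "fraction": frac}
            )
    rows.append({"age_start": 100, "age_end": 120, "sex": "M", "fraction": 0.25})
    rows.append({"age_start": 100, "age_end": 120, "sex": "F", "fraction": 0.34})
    return CauseFractionTable(pd.DataFrame(rows))
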