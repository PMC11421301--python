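"""Age-grid data structures for twin-pair longitudinal traits.

Observations are placed on a coarse chronological-age grid (by default
2-year bins from age 50 up to, but excluding, age 90).  The analysis unit
is the twin pair: both members' trait series are stacked into one vector
so that family-level random effects can induce cross-twin covariance.
Singletons are carried as pairs whose co-twin has no observations.

The frailty index (FI) follows the deficit-accumulation model: the share
of health deficits present out of those assessed, expressed in percent.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AgeGrid",
    "DeficitRecord",
    "BinObservation",
    "PersonTrajectory",
    "PairDataset",
    "assign_age_bin",
    "compute_frailty_index",
    "build_pair_dataset",
]


@dataclass(frozen=True)
class AgeGrid:
    """Half-open, contiguous age bins ``[start + w*t, start + w*(t+1))``.

    Defaults cover ages [50, 52) through [88, 90); observations at or
    beyond the upper edge (sparse very old ages) are unassignable and
    dropped rather than pooled into the last bin.
    """

    start_age: float = 50.0
    bin_width: float = 2.0
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.n_bins < 1:
            raise ValueError("AgeGrid needs positive bin_width and n_bins >= 1")

    @property
    def end_age(self) -> float:
        return self.start_age + self.bin_width * self.n_bins

    def bin_start(self, t: int) -> float:
        """Lower edge of bin ``t`` — the age at which that bin's latent score is defined."""
        if not 0 <= t < self.n_bins:
            raise IndexError(f"bin index {t} outside [0, {self.n_bins})")
        return self.start_age + self.bin_width * t

    def ages(self) -> np.ndarray:
        """Lower edges of all bins (the plotting axis for trajectories)."""
        return self.start_age + self.bin_width * np.arange(self.n_bins)

    def assign(self, age: float) -> int | None:
        return assign_age_bin(age, self)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AgeGrid":
        return cls(**dict(d))


def assign_age_bin(age: float, grid: AgeGrid = AgeGrid()) -> int | None:
    """Map a chronological age to its grid bin, or ``None`` if out of range.

    Bins are half-open so a boundary age belongs to the bin it starts
    (age 50.0 -> bin 0; age 90.0 -> unassignable on the default grid).
    """
    age = float(age)
    if not math.isfinite(age):
        raise ValueError(f"age must be finite, got {age!r}")
    if age < grid.start_age or age >= grid.end_age:
        return None
    t = int((age - grid.start_age) // grid.bin_width)
    # floating point at the very top edge
    return min(t, grid.n_bins - 1)


@dataclass
class DeficitRecord:
    """One person-wave's deficit items; ``nan`` marks an unavailable item."""

    person_id: str
    wave: str | int
    items: np.ndarray

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=float)
        avail = self.items[~np.isnan(self.items)]
        if avail.size and (avail.min() < 0 or avail.max() > 1):
            raise ValueError("deficit items must lie in [0, 1] (nan = unavailable)")


def compute_frailty_index(record: DeficitRecord) -> float:
    """Frailty index in percent: 100 x (sum of deficits) / (items considered).

    Unavailable items shrink the denominator; the score is undefined when
    no items are available.
    """
    avail = ~np.isnan(record.items)
    n = int(avail.sum())
    if n == 0:
        raise ValueError(
            f"FI undefined for person {record.person_id} wave {record.wave}: "
            "no deficit items available"
        )
    return 100.0 * float(record.items[avail].sum()) / n


@dataclass
class BinObservation:
    """Trait values observed in one age bin, with the raw age retained."""

    age: float
    values: dict[str, float] = field(default_factory=dict)


@dataclass
class PersonTrajectory:
    person_id: str
    pair_id: str
    sex: int  # 0 = man, 1 = woman
    zygosity: str = "unknown"  # MZ / DZ / unknown; metadata only
    observations: dict[int, BinObservation] = field(default_factory=dict)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def first_observation(self) -> tuple[int, BinObservation] | None:
        """Earliest observed bin (the person's baseline), or None."""
        if not self.observations:
            return None
        t = min(self.observations)
        return t, self.observations[t]


@dataclass
class PairDataset:
    """Pair-structured dataset: the unit of likelihood evaluation.

    ``pairs`` holds (twin A, twin B); a singleton's co-twin is a
    trajectory with zero observations.  ``pace_rescaled`` records that a
    pace-of-aging trait has been put on a x10 scale (done at most once).
    """

    grid: AgeGrid
    pairs: list[tuple[PersonTrajectory, PersonTrajectory]]
    trait_labels: tuple[str, ...]
    pace_rescaled: bool = False

    def persons(self) -> Iterable[PersonTrajectory]:
        for a, b in self.pairs:
            yield a
            yield b

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_persons(self) -> int:
        """Persons with at least one observation (placeholder co-twins excluded)."""
        return sum(1 for p in self.persons() if p.n_observations > 0)

    def summary(self) -> dict:
        per_bin = {t: 0 for t in range(self.grid.n_bins)}
        n_obs = 0
        for p in self.persons():
            for t in p.observations:
                per_bin[t] += 1
                n_obs += 1
        return {
            "n_persons": self.n_persons,
            "n_pairs": self.n_pairs,
            "n_person_bins": n_obs,
            "trait_labels": list(self.trait_labels),
            "pace_rescaled": self.pace_rescaled,
            "observations_per_bin": per_bin,
        }

    def to_long_frame(self) -> pd.DataFrame:
        """Canonical long-format export (one row per person-bin)."""
        rows = []
        for p in self.persons():
            if p.n_observations == 0:
                continue
            for t in sorted(p.observations):
                obs = p.observations[t]
                row = {
                    "person_id": p.person_id,
                    "pair_id": p.pair_id,
                    "sex": p.sex,
                    "zygosity": p.zygosity,
                    "age": obs.age,
                }
                for trait in self.trait_labels:
                    row[trait] = obs.values.get(trait, np.nan)
                rows.append(row)
        return pd.DataFrame(rows)


DEFAULT_COLUMNS = {
    "person_id": "person_id",
    "pair_id": "pair_id",
    "sex": "sex",
    "age": "age",
    "zygosity": "zygosity",
}


def build_pair_dataset(
    records: pd.DataFrame,
    grid: AgeGrid = AgeGrid(),
    traits: Sequence[str] = ("fi", "clock"),
    columns: Mapping[str, str] | None = None,
    rescale_pace: bool = False,
    pace_trait: str = "clock",
    pace_rescaled: bool = False,
) -> PairDataset:
    """Assemble a long-format table (one row per person-wave) into pairs.

    Rows with unassignable ages are dropped (count logged).  If two waves
    of one person land in the same bin, the chronologically first is kept
    and a warning logged.  With ``rescale_pace`` the ``pace_trait`` column
    is multiplied by 10 (exactly once; tracked by the dataset flag).
    ``pace_rescaled`` asserts that the input is already on the x10 scale.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    trait_cols = {t: (columns or {}).get(t, t) for t in traits}

    required = [cols["person_id"], cols["pair_id"], cols["sex"], cols["age"]]
    for c in required + list(trait_cols.values()):
        if c not in records.columns:
            raise ValueError(f"missing required column {c!r}")

    if rescale_pace and pace_rescaled:
        raise ValueError("input marked already rescaled; refusing to rescale twice")
    records = records.copy()
    if rescale_pace:
        if pace_trait not in traits:
            raise ValueError(f"pace trait {pace_trait!r} not among traits {traits}")
        records[trait_cols[pace_trait]] = records[trait_cols[pace_trait]] * 10.0

    # a person must belong to exactly one pair
    pair_per_person = records.groupby(cols["person_id"])[cols["pair_id"]].nunique()
    bad = pair_per_person[pair_per_person > 1]
    if len(bad):
        raise ValueError(
            f"person(s) appear under multiple pair_ids: {list(bad.index)[:5]}"
        )

    persons: dict[str, PersonTrajectory] = {}
    n_dropped = 0
    n_dup = 0
    for _, row in records.sort_values(cols["age"], kind="stable").iterrows():
        pid = str(row[cols["person_id"]])
        age = float(row[cols["age"]])
        t = assign_age_bin(age, grid)
        if t is None:
            n_dropped += 1
            continue
        if pid not in persons:
            persons[pid] = PersonTrajectory(
                person_id=pid,
                pair_id=str(row[cols["pair_id"]]),
                sex=int(row[cols["sex"]]),
                zygosity=str(row[cols["zygosity"]]) if cols["zygosity"] in records.columns else "unknown",
            )
        traj = persons[pid]
        if t in traj.observations:
            n_dup += 1
            logger.warning(
                "person %s: second observation at age %.2f falls in bin %d; "
                "keeping the earlier wave (age %.2f)",
                pid, age, t, traj.observations[t].age,
            )
            continue
        values = {}
        for trait, col in trait_cols.items():
            v = row[col]
            if pd.notna(v):
                values[trait] = float(v)
        traj.observations[t] = BinObservation(age=age, values=values)

    if n_dropped:
        logger.info("dropped %d observation(s) with ages outside the grid", n_dropped)
    if n_dup:
        logger.warning("resolved %d within-bin duplicate observation(s) (kept first)", n_dup)

    by_pair: dict[str, list[PersonTrajectory]] = {}
    for traj in persons.values():
        by_pair.setdefault(traj.pair_id, []).append(traj)

    pairs: list[tuple[PersonTrajectory, PersonTrajectory]] = []
    for pair_id in sorted(by_pair):
        members = sorted(by_pair[pair_id], key=lambda p: p.person_id)
        if len(members) > 2:
            raise ValueError(f"pair {pair_id!r} has {len(members)} members")
        if len(members) == 1:
            # singleton: placeholder co-twin with no observations
            ghost = PersonTrajectory(
                person_id=f"{members[0].person_id}::cotwin_missing",
                pair_id=pair_id,
                sex=members[0].sex,
                zygosity=members[0].zygosity,
            )
            members.append(ghost)
        pairs.append((members[0], members[1]))

    return PairDataset(
        grid=grid,
        pairs=pairs,
        trait_labels=tuple(traits),
        pace_rescaled=rescale_pace or pace_rescaled,
    )
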