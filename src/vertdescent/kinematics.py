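"""Footfall-based gait kinematics.

Turns per-limb touchdown/lift-off event times into duty factors, girdle
lags, limb phases, stance periods, speeds, and a Hildebrand-style gait
label per stride cycle.

Conventions
-----------
All timing quantities are expressed as percentages:

* duty factor -- percentage of a limb's stride duration spent in contact
  with the support;
* girdle lag -- temporal lag between left and right contact midpoints of
  one girdle, modulo the stride duration;
* limb phase -- percentage of stride duration separating a hindlimb
  contact midpoint from its ipsilateral forelimb's;
* stance period -- minimal circular separation of a girdle's left and
  right contact midpoints as a percentage of the pair's mean contact
  duration (used to classify asymmetrical gaits).

A stride is *symmetrical* when both girdle lags lie in [40, 60]% of the
stride duration; symmetrical strides are categorized by mean limb phase
(LSLC/LSDC/DSDC/DSLC quartiles), asymmetrical strides by the fore- and
hindlimb stance periods (bound / half-bound / gallop at the 10% cut).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LIMBS",
    "SYMMETRICAL_GAITS",
    "ASYMMETRICAL_GAITS",
    "LimbStride",
    "StrideCycle",
    "GaitLabel",
    "Bout",
    "InvalidEventError",
    "duty_factor",
    "girdle_lag",
    "mean_limb_phase",
    "stance_period",
    "classify_gait",
    "bout_speeds",
    "read_footfall_table",
    "cycles_from_table",
    "gait_table",
]

LIMBS = ("LF", "RF", "LH", "RH")
SYMMETRICAL_GAITS = ("LSLC", "LSDC", "DSDC", "DSLC")
ASYMMETRICAL_GAITS = ("bound", "half_bound", "gallop")
GAIT_CATEGORIES = SYMMETRICAL_GAITS + ASYMMETRICAL_GAITS

STRATEGIES = ("head_first", "side", "tail_first")
SUPPORTS = ("small", "medium", "large")


class InvalidEventError(ValueError):
    """Raised when footfall event times violate ordering or positivity."""


@dataclass(frozen=True)
class LimbStride:
    """One limb's contact cycle: touchdown, lift-off, next touchdown (s)."""

    limb: str
    touchdown: float
    liftoff: float
    next_touchdown: float

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise InvalidEventError(f"unknown limb {self.limb!r}; expected one of {LIMBS}")
        t = (self.touchdown, self.liftoff, self.next_touchdown)
        if not all(np.isfinite(t)):
            raise InvalidEventError(f"non-finite event times {t} for limb {self.limb}")
        if min(t) < 0:
            raise InvalidEventError(f"negative event times {t} for limb {self.limb}")
        if not (self.touchdown < self.liftoff < self.next_touchdown):
            raise InvalidEventError(
                f"event times must satisfy touchdown < liftoff < next touchdown, got {t}"
            )

    @property
    def stride_duration(self) -> float:
        return self.next_touchdown - self.touchdown

    @property
    def contact_duration(self) -> float:
        return self.liftoff - self.touchdown

    @property
    def midpoint(self) -> float:
        """Temporal midpoint of the contact interval."""
        return 0.5 * (self.touchdown + self.liftoff)

    def shifted(self, dt: float) -> "LimbStride":
        return LimbStride(self.limb, self.touchdown + dt, self.liftoff + dt, self.next_touchdown + dt)


def duty_factor(stride: LimbStride) -> float:
    """Percentage of stride duration the limb is in contact with the support."""
    return 100.0 * stride.contact_duration / stride.stride_duration


def girdle_lag(mid_left: float, mid_right: float, reference_duration: float) -> float:
    """Left-to-right midpoint lag, modulo the stride duration, in [0, 100)%."""
    if reference_duration <= 0:
        raise InvalidEventError(f"reference duration must be positive, got {reference_duration}")
    return 100.0 * ((mid_right - mid_left) % reference_duration) / reference_duration


def stance_period(left: LimbStride, right: LimbStride, reference_duration: float | None = None) -> float:
    """Temporal separation of a girdle's limbs, in % of their mean contact duration.

    The separation of the two contact midpoints is taken as the minimal
    circular distance over the stride period, so near-synchronous limbs on
    either side of a stride boundary still read as synchronous.
    """
    if left.limb[1] != right.limb[1] or {left.limb[0], right.limb[0]} != {"L", "R"}:
        raise InvalidEventError(f"{left.limb}/{right.limb} are not the two limbs of one girdle")
    mean_contact = 0.5 * (left.contact_duration + right.contact_duration)
    if mean_contact <= 0:
        raise InvalidEventError("zero contact duration")
    if reference_duration is None:
        reference_duration = 0.5 * (left.stride_duration + right.stride_duration)
    sep = abs(left.midpoint - right.midpoint) % reference_duration
    sep = min(sep, reference_duration - sep)
    return 100.0 * sep / mean_contact


@dataclass(frozen=True)
class GaitLabel:
    symmetry: bool
    category: str

    def __post_init__(self) -> None:
        if self.category not in GAIT_CATEGORIES:
            raise ValueError(f"unknown gait category {self.category!r}")
        if self.symmetry != (self.category in SYMMETRICAL_GAITS):
            raise ValueError(f"symmetry flag inconsistent with category {self.category!r}")


@dataclass
class StrideCycle:
    """A full stride: one :class:`LimbStride` per limb plus derived quantities.

    ``reference_duration`` is the arithmetic mean of the four per-limb
    stride durations (robust to per-limb timing noise and symmetric in
    the limbs).
    """

    strides: Mapping[str, LimbStride]
    reference_duration: float = field(init=False)

    def __post_init__(self) -> None:
        missing = [limb for limb in LIMBS if limb not in self.strides]
        if missing:
            raise InvalidEventError(f"stride cycle is missing limbs {missing}")
        self.strides = {limb: self.strides[limb] for limb in LIMBS}
        self.reference_duration = float(
            np.mean([s.stride_duration for s in self.strides.values()])
        )

    @property
    def duty_factors(self) -> dict[str, float]:
        return {limb: duty_factor(s) for limb, s in self.strides.items()}

    @property
    def mean_duty_factor(self) -> float:
        return float(np.mean(list(self.duty_factors.values())))

    @property
    def fore_lag(self) -> float:
        return girdle_lag(
            self.strides["LF"].midpoint, self.strides["RF"].midpoint, self.reference_duration
        )

    @property
    def hind_lag(self) -> float:
        return girdle_lag(
            self.strides["LH"].midpoint, self.strides["RH"].midpoint, self.reference_duration
        )

    @property
    def mean_limb_phase(self) -> float:
        return mean_limb_phase(self)

    @property
    def fore_stance_period(self) -> float:
        return stance_period(self.strides["LF"], self.strides["RF"], self.reference_duration)

    @property
    def hind_stance_period(self) -> float:
        return stance_period(self.strides["LH"], self.strides["RH"], self.reference_duration)


def mean_limb_phase(cycle: StrideCycle) -> float:
    """Mean of the left and right limb phases, from contact-interval midpoints.

    The left limb phase is the (modular) delay of the left forelimb's
    contact midpoint after the left hindlimb's, in % of the stride
    duration; the right phase is analogous.
    """
    d = cycle.reference_duration
    left = girdle_lag(cycle.strides["LH"].midpoint, cycle.strides["LF"].midpoint, d)
    right = girdle_lag(cycle.strides["RH"].midpoint, cycle.strides["RF"].midpoint, d)
    return 0.5 * (left + right)


def classify_gait(cycle: StrideCycle) -> GaitLabel:
    """Assign the Hildebrand-style gait category of one stride cycle.

    Symmetrical strides (both girdle lags in [40, 60]%) are split by mean
    limb phase: [0, 25) LSLC, [25, 50) LSDC, [50, 75) DSDC, [75, 100]
    DSLC. Asymmetrical strides are split by stance periods, evaluating
    bound (both <= 10), then half-bound (exactly one <= 10), then gallop;
    a stance period of exactly 10% therefore binds to the synchronous side.
    """
    symmetric = 40.0 <= cycle.fore_lag <= 60.0 and 40.0 <= cycle.hind_lag <= 60.0
    if symmetric:
        phase = cycle.mean_limb_phase
        if phase < 25.0:
            category = "LSLC"
        elif phase < 50.0:
            category = "LSDC"
        elif phase < 75.0:
            category = "DSDC"
        else:
            category = "DSLC"
        return GaitLabel(True, category)
    fore_sync = cycle.fore_stance_period <= 10.0
    hind_sync = cycle.hind_stance_period <= 10.0
    if fore_sync and hind_sync:
        category = "bound"
    elif fore_sync or hind_sync:
        category = "half_bound"
    else:
        category = "gallop"
    return GaitLabel(False, category)


def bout_speeds(distance: float, duration: float, body_length: float) -> tuple[float, float]:
    """Absolute speed (m/s) and relative speed (body lengths/s) of a bout."""
    for name, value in (("distance", distance), ("duration", duration), ("body_length", body_length)):
        if not np.isfinite(value) or value <= 0:
            raise InvalidEventError(f"{name} must be positive and finite, got {value}")
    speed = distance / duration
    return speed, speed / body_length


@dataclass(frozen=True)
class Bout:
    """A scored ascent or descent with its speed metrics."""

    species: str
    individual: str
    direction: str
    strategy: str
    support: str
    distance: float
    duration: float
    body_length: float

    def __post_init__(self) -> None:
        if self.direction not in ("ascent", "descent"):
            raise ValueError(f"direction must be ascent/descent, got {self.direction!r}")
        if self.direction == "ascent" and self.strategy != "not_applicable":
            raise ValueError("ascents carry no descent strategy (use 'not_applicable')")
        if self.direction == "descent" and self.strategy not in STRATEGIES:
            raise ValueError(f"unknown descent strategy {self.strategy!r}")
        bout_speeds(self.distance, self.duration, self.body_length)  # validates positivity

    @property
    def speed(self) -> float:
        return self.distance / self.duration

    @property
    def relative_speed(self) -> float:
        return self.speed / self.body_length


# ---------------------------------------------------------------------------
# delimited-text I/O

FOOTFALL_COLUMNS = [
    "species", "individual", "support", "direction", "strategy", "limb",
    "td_frame", "lo_frame", "next_td_frame", "fps", "distance_m", "body_length_m",
]


def read_footfall_table(path: str | Path) -> pd.DataFrame:
    """Read a comma-separated footfall event table (frame + fps encoding)."""
    df = pd.read_csv(path)
    missing = [c for c in FOOTFALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"footfall table is missing columns {missing}")
    return df


def cycles_from_table(df: pd.DataFrame) -> pd.DataFrame:
    """Group limb rows into stride cycles and attach a :class:`StrideCycle` each.

    Rows are grouped by the ``bout`` column when present; otherwise
    consecutive blocks of four limb rows sharing identical bout metadata
    form one cycle. Frame counts are converted to seconds using ``fps``.
    """
    df = df.copy()
    meta_cols = ["species", "individual", "support", "direction", "strategy"]
    if "bout" not in df.columns:
        block = (df[meta_cols] != df[meta_cols].shift()).any(axis=1).cumsum()
        df["bout"] = block.astype(str) + "/" + (df.groupby(block).cumcount() // 4).astype(str)
    records = []
    for (bout, *meta), grp in df.groupby(["bout"] + meta_cols, sort=False):
        if len(grp) % 4:
            raise InvalidEventError(
                f"bout {bout!r} has {len(grp)} limb rows; a multiple of 4 expected"
            )
        grp = grp.reset_index(drop=True)
        for _, stride_rows in grp.groupby(grp.index // 4):
            strides = {}
            for _, row in stride_rows.iterrows():
                fps = float(row["fps"])
                strides[row["limb"]] = LimbStride(
                    row["limb"],
                    float(row["td_frame"]) / fps,
                    float(row["lo_frame"]) / fps,
                    float(row["next_td_frame"]) / fps,
                )
            cycle = StrideCycle(strides)
            rec = dict(zip(meta_cols, meta))
            rec.update(
                bout=bout,
                distance_m=float(stride_rows["distance_m"].iloc[0]),
                body_length_m=float(stride_rows["body_length_m"].iloc[0]),
                cycle=cycle,
            )
            records.append(rec)
    return pd.DataFrame.from_records(records)


def gait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-stride kinematic summary (duty factors, gait label, speeds).

    ``df`` is a raw footfall event table as read by
    :func:`read_footfall_table`.
    """
    cycles = cycles_from_table(df)
    rows = []
    for rec in cycles.itertuples(index=False):
        cycle: StrideCycle = rec.cycle
        label = classify_gait(cycle)
        speed, rel_speed = bout_speeds(rec.distance_m, cycle.reference_duration, rec.body_length_m)
        rows.append(
            {
                "species": rec.species,
                "individual": rec.individual,
                "support": rec.support,
                "direction": rec.direction,
                "strategy": rec.strategy,
                "bout": rec.bout,
                "mean_duty_factor": cycle.mean_duty_factor,
                "fore_lag": cycle.fore_lag,
                "hind_lag": cycle.hind_lag,
                "mean_limb_phase": cycle.mean_limb_phase if label.symmetry else np.nan,
                "fore_stance_period": cycle.fore_stance_period,
                "hind_stance_period": cycle.hind_stance_period,
                "symmetry": label.symmetry,
                "gait": label.category,
                "speed_m_s": speed,
                "relative_speed_bl_s": rel_speed,
            }
        )
    return pd.DataFrame(rows)
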