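"""MRF acquisition schedules: saturation-encoded protocol definitions.

A schedule is a fixed-length list of saturation blocks. Two in-vivo encoding
strategies are supported, mirroring standard CEST/MT fingerprinting practice:

* ``mt-encode``   — both saturation power and frequency offset vary, with
  offsets restricted to 6-14 ppm where the broad semisolid MT pool dominates
  and mobile CEST/NOE pools do not contribute.
* ``rnoe-encode`` — the offset is fixed at the rNOE resonance (-3.5 ppm for
  brain aliphatic protons, -1 ppm for glycogen glycoNOE) while the power is
  pseudo-randomly varied.

Phantom protocols (``phantom-glyco``, ``phantom-bsa``) are rnoe-encode
schedules at the respective fixed offsets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .bloch_mcconnell import SaturationEvent

__all__ = [
    "MRFSchedule",
    "generate_rnoe_schedule",
    "generate_mt_schedule",
    "validate_schedule",
    "save_schedule",
    "load_schedule",
    "schedule_hash",
]

PROTOCOL_LABELS = ("mt-encode", "rnoe-encode", "phantom-glyco", "phantom-bsa")

#: Offset band (|ppm|) contaminated by mobile-proton CEST/NOE contributions;
#: mt-encode schedules must stay outside it.
MT_OFFSET_RANGE_PPM = (6.0, 14.0)

#: Defaults: CW saturation of 2.5 s with 1.0 s recovery (preclinical); the
#: clinical variant uses a 13 x 100 ms spin-lock train at 50% duty cycle.
DEFAULT_T_SAT_S = 2.5
DEFAULT_RECOVERY_S = 1.0
CLINICAL_TRAIN = {"n_pulses": 13, "pulse_duration_s": 0.1, "duty_cycle": 0.5}


@dataclass(frozen=True)
class MRFSchedule:
    """A saturation-encoded MRF protocol of ``n_iterations`` blocks."""

    protocol_label: str
    field_tesla: float
    b1_uT: tuple[float, ...]
    offset_ppm: tuple[float, ...]
    t_sat_s: float = DEFAULT_T_SAT_S
    recovery_s: float = DEFAULT_RECOVERY_S
    shape: str = "cw"
    n_pulses: int | None = None
    pulse_duration_s: float | None = None
    duty_cycle: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "b1_uT", tuple(float(b) for b in self.b1_uT))
        object.__setattr__(
            self, "offset_ppm", tuple(float(o) for o in self.offset_ppm)
        )
        if len(self.b1_uT) != len(self.offset_ppm):
            raise ValueError("b1_uT and offset_ppm must have equal length")
        if len(self.b1_uT) < 1:
            raise ValueError("schedule needs at least one iteration")

    @property
    def n_iterations(self) -> int:
        return len(self.b1_uT)

    def event(self, i: int) -> SaturationEvent:
        kwargs = {}
        if self.shape == "pulse-train":
            kwargs = {
                "n_pulses": self.n_pulses,
                "pulse_duration_s": self.pulse_duration_s,
                "duty_cycle": self.duty_cycle,
            }
        return SaturationEvent(
            shape=self.shape,
            b1_uT=self.b1_uT[i],
            duration_s=self.t_sat_s,
            offset_ppm=self.offset_ppm[i],
            **kwargs,
        )

    def events(self) -> Iterator[tuple[SaturationEvent, float]]:
        """Yield (saturation event, recovery time) per iteration."""
        for i in range(self.n_iterations):
            yield self.event(i), self.recovery_s

    def to_dict(self) -> dict:
        d = {
            "protocol_label": self.protocol_label,
            "field_tesla": self.field_tesla,
            "t_sat_s": self.t_sat_s,
            "recovery_s": self.recovery_s,
            "shape": self.shape,
            "iterations": [
                {"b1_uT": b, "offset_ppm": o}
                for b, o in zip(self.b1_uT, self.offset_ppm)
            ],
        }
        if self.shape == "pulse-train":
            d.update(
                n_pulses=self.n_pulses,
                pulse_duration_s=self.pulse_duration_s,
                duty_cycle=self.duty_cycle,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MRFSchedule":
        its = d["iterations"]
        return cls(
            protocol_label=d["protocol_label"],
            field_tesla=d["field_tesla"],
            b1_uT=tuple(it["b1_uT"] for it in its),
            offset_ppm=tuple(it["offset_ppm"] for it in its),
            t_sat_s=d.get("t_sat_s", DEFAULT_T_SAT_S),
            recovery_s=d.get("recovery_s", DEFAULT_RECOVERY_S),
            shape=d.get("shape", "cw"),
            n_pulses=d.get("n_pulses"),
            pulse_duration_s=d.get("pulse_duration_s"),
            duty_cycle=d.get("duty_cycle"),
        )


def generate_rnoe_schedule(
    n: int = 30,
    offset_ppm: float = -3.5,
    b1_range_uT: tuple[float, float] = (0.0, 4.0),
    seed: int = 0,
    *,
    protocol_label: str = "rnoe-encode",
    field_tesla: float = 7.0,
    first_unsaturated: bool = True,
    **schedule_kwargs,
) -> MRFSchedule:
    """Fixed-offset, pseudo-random-power rNOE encoding schedule.

    Powers are drawn uniformly from ``b1_range_uT`` with a seeded generator;
    by default the first iteration is forced to B1 = 0 as an unsaturated
    reference anchor.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = b1_range_uT
    if hi <= lo:
        raise ValueError("b1_range_uT must be a nonempty (low, high) interval")
    rng = np.random.default_rng(seed)
    powers = rng.uniform(lo, hi, size=n)
    if first_unsaturated:
        powers[0] = 0.0
    return MRFSchedule(
        protocol_label=protocol_label,
        field_tesla=field_tesla,
        b1_uT=tuple(powers),
        offset_ppm=(offset_ppm,) * n,
        **schedule_kwargs,
    )


def generate_mt_schedule(
    n: int = 30,
    offset_range_ppm: tuple[float, float] = MT_OFFSET_RANGE_PPM,
    b1_range_uT: tuple[float, float] = (0.0, 4.0),
    seed: int = 0,
    *,
    field_tesla: float = 7.0,
    first_unsaturated: bool = True,
    **schedule_kwargs,
) -> MRFSchedule:
    """Semisolid-MT encoding schedule: power and offset both pseudo-random.

    Offsets are uniform in ``offset_range_ppm`` (default 6-14 ppm, away from
    mobile-proton contributions); a degenerate range (a, a) yields a constant
    offset.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo_b, hi_b = b1_range_uT
    if hi_b <= lo_b:
        raise ValueError("b1_range_uT must be a nonempty (low, high) interval")
    lo_o, hi_o = offset_range_ppm
    if hi_o < lo_o:
        raise ValueError("offset_range_ppm must satisfy low <= high")
    rng = np.random.default_rng(seed)
    powers = rng.uniform(lo_b, hi_b, size=n)
    offsets = (
        np.full(n, lo_o) if hi_o == lo_o else rng.uniform(lo_o, hi_o, size=n)
    )
    if first_unsaturated:
        powers[0] = 0.0
    return MRFSchedule(
        protocol_label="mt-encode",
        field_tesla=field_tesla,
        b1_uT=tuple(powers),
        offset_ppm=tuple(offsets),
        **schedule_kwargs,
    )


def validate_schedule(schedule: MRFSchedule) -> list[str]:
    """Return a list of invariant violations (empty list = compliant)."""
    v: list[str] = []
    if schedule.protocol_label not in PROTOCOL_LABELS:
        v.append(f"unknown protocol_label {schedule.protocol_label!r}")
    if schedule.n_iterations < 1:
        v.append("n_iterations < 1")
    for i, b in enumerate(schedule.b1_uT):
        if b < 0:
            v.append(f"b1_uT < 0 at iteration {i}")
    if schedule.protocol_label in ("rnoe-encode", "phantom-glyco", "phantom-bsa"):
        distinct = sorted(set(schedule.offset_ppm))
        if len(distinct) > 1:
            bad = [
                i
                for i, o in enumerate(schedule.offset_ppm)
                if o != schedule.offset_ppm[0]
            ]
            v.append(
                f"{schedule.protocol_label} requires a single fixed offset; "
                f"iterations {bad} differ from iteration 0"
            )
    if schedule.protocol_label == "mt-encode":
        lo, hi = MT_OFFSET_RANGE_PPM
        for i, o in enumerate(schedule.offset_ppm):
            if not lo <= o <= hi:
                v.append(
                    f"mt-encode offset {o} ppm outside [{lo}, {hi}] at "
                    f"iteration {i} (CEST-contaminated band)"
                )
    if schedule.shape == "pulse-train":
        try:
            schedule.event(0)
        except ValueError as e:
            v.append(str(e))
    return v


def save_schedule(schedule: MRFSchedule, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(schedule.to_dict(), sort_keys=False), encoding="utf-8"
    )


def load_schedule(path: str | Path) -> MRFSchedule:
    return MRFSchedule.from_dict(
        yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    )


def schedule_hash(schedule: MRFSchedule) -> str:
    """Stable provenance hash of the schedule contents."""
    blob = yaml.safe_dump(schedule.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
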