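"""Trapezoidal pulse-width stimulation sequences.

A session is built from repeated cycles of ramp-up / plateau / ramp-down /
rest.  During identification the plateau pulse widths sweep linearly over a
fraction range of the stimulator maximum; during prediction they are drawn
i.i.d. uniform from a (different) fraction range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import NDArray

#: Hard stimulator pulse-width cap, us.
PW_CAP_US = 350.0


@dataclass(frozen=True)
class ProtocolConfig:
    """Configuration of one stimulation-sequence phase."""

    f_stim: float = 40.0
    pw_max: float = PW_CAP_US
    ramp_up_s: float = 0.5
    plateau_s: float = 1.0
    ramp_down_s: float = 0.5
    rest_s: float = 2.0
    n_cycles: int = 18
    phase: str = "identification"
    id_range: tuple[float, float] = (0.40, 1.00)
    pred_range: tuple[float, float] = (0.50, 1.00)
    seed: int = 0
    amplitude_ma: float = 30.0  # carried as metadata only; PW is the command

    def __post_init__(self) -> None:
        if not (1.0 <= self.f_stim <= 1000.0):
            raise ValueError("f_stim outside stimulator range [1, 1000] Hz")
        if not (0 < self.pw_max <= PW_CAP_US):
            raise ValueError(f"pw_max must lie in (0, {PW_CAP_US}] us")
        for name in ("ramp_up_s", "plateau_s", "ramp_down_s", "rest_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.phase not in ("identification", "prediction"):
            raise ValueError("phase must be 'identification' or 'prediction'")
        for rng in (self.id_range, self.pred_range):
            if not (0 < rng[0] <= rng[1] <= 1):
                raise ValueError("fraction ranges must satisfy 0 < lo <= hi <= 1")

    @property
    def cycle_period_s(self) -> float:
        return self.ramp_up_s + self.plateau_s + self.ramp_down_s + self.rest_s

    @property
    def loops_per_cycle(self) -> int:
        return int(math.floor(self.cycle_period_s * self.f_stim + 0.5))


@dataclass(frozen=True)
class ProtocolSequence:
    """Per-loop pulse-width schedule produced by :func:`build_sequence`."""

    t: NDArray[np.float64]  # loop (pulse) onset times, s
    pw: NDArray[np.float64]  # commanded pulse width per loop, us
    cycle_id: NDArray[np.int64]
    phase_label: NDArray[np.object_]  # "identification" | "prediction" per loop
    f_stim: float

    def __len__(self) -> int:
        return int(self.t.size)

    def shifted(self, dt: float) -> "ProtocolSequence":
        return ProtocolSequence(self.t + dt, self.pw, self.cycle_id, self.phase_label, self.f_stim)


def concat_sequences(first: ProtocolSequence, second: ProtocolSequence) -> ProtocolSequence:
    """Append ``second`` after ``first``, shifting its clock and cycle ids."""
    if first.f_stim != second.f_stim:
        raise ValueError("cannot concatenate sequences with different f_stim")
    offset = first.t[-1] + 1.0 / first.f_stim if len(first) else 0.0
    shifted = second.shifted(offset)
    return ProtocolSequence(
        t=np.concatenate([first.t, shifted.t]),
        pw=np.concatenate([first.pw, shifted.pw]),
        cycle_id=np.concatenate([first.cycle_id, second.cycle_id + (first.cycle_id[-1] + 1 if len(first) else 0)]),
        phase_label=np.concatenate([first.phase_label, second.phase_label]),
        f_stim=first.f_stim,
    )


def trapezoid_pw(t: float, plateau_pw: float, cfg: ProtocolConfig) -> float:
    """Pulse width (us) at time ``t`` within one trapezoidal cycle.

    Linear 0 -> plateau over the ramp-up, plateau held, linear plateau -> 0
    over the ramp-down, zero during rest; continuous at segment joins.
    """
    if plateau_pw > cfg.pw_max:
        raise ValueError("PW exceeds stimulator limit")
    if not (0 <= t < cfg.cycle_period_s):
        raise ValueError("t outside cycle period")
    t1 = cfg.ramp_up_s
    t2 = t1 + cfg.plateau_s
    t3 = t2 + cfg.ramp_down_s
    if t < t1:
        return plateau_pw * (t / cfg.ramp_up_s) if cfg.ramp_up_s > 0 else plateau_pw
    if t < t2:
        return plateau_pw
    if t < t3:
        return plateau_pw * (1.0 - (t - t2) / cfg.ramp_down_s) if cfg.ramp_down_s > 0 else 0.0
    return 0.0


def plateau_schedule(cfg: ProtocolConfig) -> NDArray[np.float64]:
    """Per-cycle plateau pulse widths (us) for the configured phase.

    Identification: linearly spaced fractions over ``id_range``.
    Prediction: i.i.d. uniform fractions over ``pred_range`` (seeded).
    """
    if cfg.phase == "identification":
        if cfg.n_cycles == 1:
            fracs = np.array([cfg.id_range[1]])
        else:
            fracs = np.linspace(cfg.id_range[0], cfg.id_range[1], cfg.n_cycles)
    else:
        rng = np.random.default_rng(cfg.seed)
        fracs = rng.uniform(cfg.pred_range[0], cfg.pred_range[1], size=cfg.n_cycles)
    return fracs * cfg.pw_max


def build_sequence(cfg: ProtocolConfig) -> ProtocolSequence:
    """Sample the trapezoidal PW train at loop times (left edge of each loop)."""
    plateaus = plateau_schedule(cfg)
    n_loop = cfg.loops_per_cycle
    period = cfg.cycle_period_s
    t_all, pw_all, cyc_all = [], [], []
    for c, plat in enumerate(plateaus):
        for j in range(n_loop):
            t_in = j / cfg.f_stim
            t_all.append(c * period + t_in)
            pw_all.append(trapezoid_pw(min(t_in, np.nextafter(period, 0.0)), plat, cfg))
            cyc_all.append(c)
    return ProtocolSequence(
        t=np.asarray(t_all),
        pw=np.asarray(pw_all),
        cycle_id=np.asarray(cyc_all, dtype=np.int64),
        phase_label=np.asarray([cfg.phase] * len(t_all), dtype=object),
        f_stim=cfg.f_stim,
    )


def build_session_protocol(
    id_cfg: ProtocolConfig, pred_cfg: ProtocolConfig
) -> ProtocolSequence:
    """Identification sequence followed immediately by a prediction sequence."""
    id_cfg = replace(id_cfg, phase="identification")
    pred_cfg = replace(pred_cfg, phase="prediction")
    return concat_sequences(build_sequence(id_cfg), build_sequence(pred_cfg))
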