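"""Synthetic FES-session generator with known ground truth.

Simulates the raw two-channel recording an isometric FES experiment would
produce: each stimulation pulse inserts an artifact spike and a biphasic
M-wave whose amplitude follows a saturating recruitment curve of the pulse
width, while joint torque is the response of a second-order low-pass system
driven by the activation series.  The clean (artifact- and noise-free)
per-loop MAV and torque are exposed so estimator tests have an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.signal import cont2discrete

from festorque.signal_processing import TORQUE_NM_PER_VOLT, RawRecording, _round_half_up
from festorque.stim_protocol import ProtocolSequence


@dataclass(frozen=True)
class MuscleSimParams:
    """Ground-truth parameters of the simulated muscle and sensors.

    The recruitment curve is zero below ``pw_threshold_us``, rises as a
    smoothstep and saturates at ``max_activation`` for
    ``pw >= pw_saturation_us``.  Torque follows a unit-DC-gain second-order
    low-pass response to activation, scaled by ``torque_gain_nm``.  Fatigue
    is a single exponential decay applied to both the M-wave amplitude and
    the torque gain.
    """

    pw_threshold_us: float = 50.0
    pw_saturation_us: float = 350.0
    max_activation: float = 1.0
    mwave_duration_ms: float = 15.0
    mwave_amplitude_mv: float = 1.5  # peak mV per unit activation
    mwave_delay_ms: float = 10.0  # template onset after the pulse
    artifact_amplitude_mv: float = 20.0
    artifact_duration_ms: float = 1.0
    torque_gain_nm: float = 30.0
    natural_freq_hz: float = 1.0
    damping: float = 0.9
    noise_sd_emg_mv: float = 0.0
    noise_sd_torque_nm: float = 0.0
    fatigue_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pw_threshold_us < self.pw_saturation_us):
            raise ValueError("invalid simulation config: require 0 <= threshold < saturation")
        if self.damping <= 0:
            raise ValueError("invalid simulation config: damping ratio must be positive")
        if self.noise_sd_emg_mv < 0 or self.noise_sd_torque_nm < 0:
            raise ValueError("invalid simulation config: noise SDs must be non-negative")
        if self.fatigue_rate_per_min < 0:
            raise ValueError("invalid simulation config: fatigue_rate must be non-negative")
        if self.max_activation <= 0 or self.torque_gain_nm < 0:
            raise ValueError("invalid simulation config")


@dataclass(frozen=True)
class SimulatedSession:
    """A simulated recording plus the ground truth behind it."""

    recording: RawRecording
    clean_u: NDArray[np.float64]  # per-loop MAV of the artifact/noise-free eEMG, mV
    clean_tau: NDArray[np.float64]  # per-loop torque before noise, Nm
    activation: NDArray[np.float64]  # per-loop muscle activation (dimensionless)
    clean_emg: NDArray[np.float64]  # artifact- and noise-free eEMG channel, mV
    params: MuscleSimParams
    protocol: ProtocolSequence


def recruitment_curve(pw, params: MuscleSimParams):
    """Muscle activation recruited by a pulse width (us).

    Smoothstep between threshold and saturation; monotone non-decreasing.
    """
    pw_arr = np.asarray(pw, dtype=float)
    s = np.clip(
        (pw_arr - params.pw_threshold_us) / (params.pw_saturation_us - params.pw_threshold_us),
        0.0,
        1.0,
    )
    act = params.max_activation * s * s * (3.0 - 2.0 * s)
    return float(act) if np.isscalar(pw) else act


def mwave_template(params: MuscleSimParams, f_samp: float) -> NDArray[np.float64]:
    """Biphasic M-wave shape: one cycle of a damped sine, unit peak amplitude."""
    n = max(2, int(round(params.mwave_duration_ms * f_samp / 1000.0)))
    t = np.arange(n) / (n - 1)  # 0..1 over the template duration
    w = np.sin(2.0 * np.pi * t) * np.exp(-2.0 * t)
    return w / np.max(np.abs(w))


def _artifact_template(params: MuscleSimParams, f_samp: float) -> NDArray[np.float64]:
    """Short biphasic saturation spike at the pulse instant."""
    n = max(2, int(round(params.artifact_duration_ms * f_samp / 1000.0)))
    half = n // 2
    spike = np.concatenate([np.ones(half), -np.ones(n - half)])
    decay = np.exp(-3.0 * np.arange(n) / n)
    return params.artifact_amplitude_mv * spike * decay


def _torque_dynamics(params: MuscleSimParams, dt: float):
    """Zero-order-hold discretization of the unit-gain second-order low-pass."""
    wn = 2.0 * np.pi * params.natural_freq_hz
    a = np.array([[0.0, 1.0], [-wn * wn, -2.0 * params.damping * wn]])
    b = np.array([[0.0], [wn * wn]])
    c = np.array([[1.0, 0.0]])
    d = np.array([[0.0]])
    ad, bd, cd, dd, _ = cont2discrete((a, b, c, d), dt, method="zoh")
    return ad, bd, cd


def simulate_session(
    protocol: ProtocolSequence, params: MuscleSimParams, f_samp: float = 4096.0
) -> SimulatedSession:
    """Generate the raw recording implied by a PW protocol.

    Per pulse an artifact spike plus an activation-scaled M-wave template is
    inserted at the pulse onset (the M-wave after ``mwave_delay_ms``); at
    high stimulation frequency the template outlasts the loop and spills
    into the next one, reproducing the truncation effect.  Torque is the
    second-order low-pass response to the activation series, scaled by the
    (fatigue-decayed) torque gain, emitted on the analog channel divided by
    the dynamometer scaling.  All randomness flows from ``params.seed``.
    """
    if len(protocol) == 0:
        raise ValueError("invalid simulation config: empty protocol")
    rng = np.random.default_rng(params.seed)
    f_stim = protocol.f_stim
    loop_len = _round_half_up(f_samp / f_stim)
    starts = np.array([_round_half_up(t * f_samp) for t in protocol.t], dtype=int)
    n_samples = int(starts[-1] + loop_len)

    fatigue = np.exp(-params.fatigue_rate_per_min * protocol.t / 60.0)
    activation = recruitment_curve(protocol.pw, params)

    template = mwave_template(params, f_samp)
    delay = int(round(params.mwave_delay_ms * f_samp / 1000.0))
    artifact = _artifact_template(params, f_samp)

    clean_emg = np.zeros(n_samples)
    artifact_sig = np.zeros(n_samples)
    for s, act, fat in zip(starts, activation, fatigue):
        amp = params.mwave_amplitude_mv * act * fat
        if amp > 0:
            i0 = s + delay
            i1 = min(n_samples, i0 + template.size)
            if i1 > i0:
                clean_emg[i0:i1] += amp * template[: i1 - i0]
        j1 = min(n_samples, s + artifact.size)
        artifact_sig[s:j1] += artifact[: j1 - s]

    # torque dynamics at loop rate, ZOH-held on the analog channel
    ad, bd, cd = _torque_dynamics(params, 1.0 / f_stim)
    x = np.zeros((2, 1))
    clean_tau = np.empty(len(protocol))
    for k, (act, fat) in enumerate(zip(activation, fatigue)):
        clean_tau[k] = params.torque_gain_nm * fat * float((cd @ x)[0, 0])
        x = ad @ x + bd * act

    torque_v = np.zeros(n_samples)
    for k, (s, tau_k) in enumerate(zip(starts, clean_tau)):
        e = starts[k + 1] if k + 1 < len(starts) else n_samples
        torque_v[s:e] = tau_k / TORQUE_NM_PER_VOLT

    emg = clean_emg + artifact_sig
    if params.noise_sd_emg_mv > 0:
        emg = emg + rng.normal(0.0, params.noise_sd_emg_mv, n_samples)
    if params.noise_sd_torque_nm > 0:
        torque_v = torque_v + rng.normal(
            0.0, params.noise_sd_torque_nm / TORQUE_NM_PER_VOLT, n_samples
        )

    rec = RawRecording(
        f_samp=f_samp,
        emg=emg,
        torque_voltage=torque_v,
        pulse_times=protocol.t.copy(),
        pulse_widths=protocol.pw.copy(),
        f_stim=f_stim,
    )

    # clean per-loop MAV from the artifact-free signal over the same ranges
    ends = np.empty_like(starts)
    ends[:-1] = starts[1:]
    ends[-1] = starts[-1] + loop_len
    clean_u = np.array([np.mean(np.abs(clean_emg[s:e])) for s, e in zip(starts, ends)])

    return SimulatedSession(
        recording=rec,
        clean_u=clean_u,
        clean_tau=clean_tau,
        activation=np.asarray(activation),
        clean_emg=clean_emg,
        params=params,
        protocol=protocol,
    )
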