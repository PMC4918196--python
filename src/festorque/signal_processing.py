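"""Loop-wise preprocessing of evoked-EMG and torque recordings.

Each stimulation pulse opens a "loop" of roughly ``f_samp / f_stim`` samples.
Within every loop the stimulation artifact is blanked, residual artifact
spikes are zeroed by adjacent-difference thresholding, and the loop is
reduced to two features: the mean absolute value (MAV) of the cleaned eEMG
and the mean joint torque after analog-voltage scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

#: Biodex dynamometer analog-output scaling, Nm of ankle torque per volt.
TORQUE_NM_PER_VOLT = 8.64

#: Default stimulation-artifact blanking window (ms).
DEFAULT_BLANKING_MS = 10.0

#: Default MAV smoothing window (s).
DEFAULT_SMOOTH_WINDOW_S = 0.8


def _round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RawRecording:
    """Synchronized raw eEMG / torque streams with stimulation pulse timing.

    Parameters
    ----------
    f_samp
        Sampling rate of both analog channels, Hz.
    emg
        Raw evoked-EMG samples, mV.
    torque_voltage
        Dynamometer analog output samples, V.
    pulse_times
        Stimulation pulse onsets, s, strictly increasing.
    pulse_widths
        Commanded pulse width per pulse, us.
    f_stim
        Stimulation frequency, Hz.  If ``None`` it is inferred from the
        median inter-pulse gap (requires at least two pulses).
    """

    f_samp: float
    emg: NDArray[np.float64]
    torque_voltage: NDArray[np.float64]
    pulse_times: NDArray[np.float64]
    pulse_widths: NDArray[np.float64]
    f_stim: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "emg", np.asarray(self.emg, dtype=float))
        object.__setattr__(self, "torque_voltage", np.asarray(self.torque_voltage, dtype=float))
        object.__setattr__(self, "pulse_times", np.asarray(self.pulse_times, dtype=float))
        object.__setattr__(self, "pulse_widths", np.asarray(self.pulse_widths, dtype=float))
        if self.f_samp <= 0:
            raise ValueError("f_samp must be positive")
        if self.emg.shape != self.torque_voltage.shape or self.emg.ndim != 1:
            raise ValueError("emg and torque_voltage must be 1-D arrays of equal length")
        if self.pulse_times.ndim != 1 or self.pulse_times.size == 0:
            raise ValueError("no stimulation events")
        if self.pulse_widths.shape != self.pulse_times.shape:
            raise ValueError("pulse_widths must match pulse_times in length")
        if np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse_times must be strictly increasing")
        if np.any(self.pulse_widths < 0):
            raise ValueError("pulse_widths must be non-negative")
        if self.f_stim is None and self.pulse_times.size >= 2:
            gaps = np.diff(self.pulse_times)
            object.__setattr__(self, "f_stim", float(1.0 / np.median(gaps)))

    @property
    def n_samples(self) -> int:
        return int(self.emg.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.f_samp

    def loop_length(self) -> int:
        """Nominal loop length in samples, round(f_samp / f_stim)."""
        if self.f_stim is None:
            raise ValueError("f_stim unknown: provide it explicitly for single-pulse recordings")
        return _round_half_up(self.f_samp / self.f_stim)


@dataclass(frozen=True)
class LoopFeatureSeries:
    """Per-stimulation-loop features: MAV of cleaned eEMG and mean torque."""

    k: NDArray[np.int64]
    u: NDArray[np.float64]  # MAV of eEMG per loop, mV
    tau: NDArray[np.float64]  # mean torque per loop, Nm
    pw: NDArray[np.float64]  # commanded pulse width per loop, us
    f_stim: float

    def __post_init__(self) -> None:
        for name in ("k", "u", "tau", "pw"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = self.k.size
        if not (self.u.size == self.tau.size == self.pw.size == n):
            raise ValueError("all feature arrays must share one length")
        if np.any(self.u < 0):
            raise ValueError("MAV must be non-negative")
        if not (1.0 <= self.f_stim <= 1000.0):
            raise ValueError("f_stim outside supported range [1, 1000] Hz")

    def __len__(self) -> int:
        return int(self.k.size)

    @property
    def t(self) -> NDArray[np.float64]:
        """Loop start times, s, assuming uniform stimulation."""
        return self.k / self.f_stim


def segment_loops(rec: RawRecording) -> list[tuple[int, int]]:
    """Split the stimulated span into one half-open sample range per pulse.

    Each range starts at the sample nearest the pulse onset and ends at the
    next pulse's start sample; the last loop extends one nominal loop length
    ``round(f_samp / f_stim)``.  The ranges tile the stimulated span without
    overlap.

    Raises
    ------
    ValueError
        If there are no pulses ("no stimulation events") or a loop extends
        past the end of the recording ("recording truncated").
    """
    if rec.pulse_times.size == 0:
        raise ValueError("no stimulation events")
    starts = np.array([_round_half_up(t * rec.f_samp) for t in rec.pulse_times], dtype=int)
    ends = np.empty_like(starts)
    ends[:-1] = starts[1:]
    ends[-1] = starts[-1] + rec.loop_length()
    if ends[-1] > rec.n_samples or starts[0] < 0:
        raise ValueError("recording truncated: loop extends past recording end")
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def blank_artifact(
    loop_samples: ArrayLike, window_ms: float, f_samp: float
) -> NDArray[np.float64]:
    """Zero the first ``ceil(window_ms * f_samp / 1000)`` samples of a loop.

    Suppresses the stimulation artifact that coincides with the pulse at the
    loop start.  Length is preserved; a zero window is the identity.
    """
    x = np.array(loop_samples, dtype=float)
    if window_ms < 0:
        raise ValueError("blanking window must be non-negative")
    n_blank = math.ceil(window_ms * f_samp / 1000.0)
    if n_blank >= x.size and window_ms > 0:
        raise ValueError("blanking window exceeds loop")
    x[:n_blank] = 0.0
    return x


def remove_residual_artifacts(
    loop_samples: ArrayLike,
    diff_threshold: float,
    template_half_width: int = 2,
) -> NDArray[np.float64]:
    """Zero samples around large adjacent-sample jumps.

    Wherever ``|x[i+1] - x[i]|`` exceeds ``diff_threshold``, all samples
    within ``template_half_width`` of the pair ``(i, i+1)`` are set to zero.
    Zeroing is iterated to a fixed point so that the operation is idempotent
    even when zeroing itself creates a new edge above threshold.
    """
    if diff_threshold <= 0:
        raise ValueError("invalid threshold: diff_threshold must be positive")
    hw = int(template_half_width)
    if hw < 0:
        raise ValueError("template_half_width must be non-negative")
    x = np.array(loop_samples, dtype=float)
    for _ in range(x.size + 1):
        jumps = np.flatnonzero(np.abs(np.diff(x)) > diff_threshold)
        if jumps.size == 0:
            break
        mask = np.zeros(x.size, dtype=bool)
        for i in jumps:
            mask[max(0, i - hw) : min(x.size, i + 2 + hw)] = True
        if not np.any(x[mask] != 0.0):
            break
        x[mask] = 0.0
    return x


def default_diff_threshold(
    loop_samples: ArrayLike, factor: float = 5.0, range_floor: float = 0.3
) -> float:
    """Robust default threshold for residual-artifact removal.

    ``factor`` times the median absolute adjacent difference of the loop
    (excluding the exact-zero diffs contributed by blanked runs), floored
    at ``range_floor`` times the loop's peak-to-peak range: an M-wave's
    steepest adjacent-sample step is a few percent of its range, while a
    genuine artifact edge is comparable to the full range, so the floor
    keeps smooth physiological gradients from ever being zeroed.  Returns
    ``inf`` for constant loops so thresholding becomes a no-op.
    """
    x = np.asarray(loop_samples, dtype=float)
    d = np.abs(np.diff(x))
    d = d[d > 0]
    if d.size == 0:
        return float("inf")
    med = float(np.median(d))
    if med <= 0:
        return float("inf")
    return max(factor * med, range_floor * float(np.ptp(x)))


def scale_torque(voltage: ArrayLike) -> NDArray[np.float64] | float:
    """Convert the dynamometer analog reading (V) to joint torque (Nm).

    Linear and sign-preserving: ``tau = 8.64 * voltage``.
    """
    v = np.asarray(voltage, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("torque voltage must be finite")
    out = TORQUE_NM_PER_VOLT * v
    return float(out) if np.isscalar(voltage) or out.ndim == 0 else out


def normalize_series(x: ArrayLike, reference_max: float) -> NDArray[np.float64]:
    """Divide a series by a fixed positive reference so the reference maps to 1."""
    if not reference_max > 0:
        raise ValueError("invalid normalization reference: must be positive")
    return np.asarray(x, dtype=float) / reference_max


def smooth_mav(u: ArrayLike, window_s: float, f_stim: float) -> NDArray[np.float64]:
    """Causal moving average of the MAV series over the last
    ``round(window_s * f_stim)`` loops.

    The window is clipped to the available history at the start of the
    series, so the output has the same length as the input and uses only
    past loops (real-time safe).
    """
    if window_s <= 0:
        raise ValueError("smoothing window must be positive")
    x = np.asarray(u, dtype=float)
    w = max(1, _round_half_up(window_s * f_stim))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(0, idx - w)
    return (csum[idx] - csum[lo]) / (idx - lo)


def compute_loop_features(
    rec: RawRecording,
    ranges: list[tuple[int, int]],
    *,
    blank_window_ms: float = DEFAULT_BLANKING_MS,
    diff_threshold: float | None = None,
    template_half_width: int = 2,
    torque_scale: float = TORQUE_NM_PER_VOLT,
    baseline_interval_s: tuple[float, float] | None = None,
) -> LoopFeatureSeries:
    """Reduce every loop to (MAV of cleaned eEMG, mean torque).

    Artifact removal (blanking, then adjacent-difference thresholding) is
    applied to the eEMG before the MAV.  The torque channel has a rest
    baseline subtracted before linear voltage-to-Nm scaling; by default the
    baseline is the mean of all samples before the first pulse (zero if the
    recording starts at the first pulse).

    Parameters
    ----------
    diff_threshold
        Residual-artifact threshold in mV.  ``None`` selects a per-loop
        robust default of 5x the median absolute adjacent difference.
    baseline_interval_s
        Optional ``(t0, t1)`` rest interval whose mean torque voltage is
        taken as the baseline.
    """
    if len(ranges) == 0:
        raise ValueError("empty loop: no ranges supplied")
    if baseline_interval_s is not None:
        i0 = int(round(baseline_interval_s[0] * rec.f_samp))
        i1 = int(round(baseline_interval_s[1] * rec.f_samp))
        baseline = float(np.mean(rec.torque_voltage[i0:i1])) if i1 > i0 else 0.0
    else:
        first = ranges[0][0]
        baseline = float(np.mean(rec.torque_voltage[:first])) if first > 0 else 0.0

    u = np.empty(len(ranges))
    tau = np.empty(len(ranges))
    for j, (s, e) in enumerate(ranges):
        if e <= s:
            raise ValueError("empty loop")
        loop = rec.emg[s:e]
        loop = blank_artifact(loop, blank_window_ms, rec.f_samp)
        thr = diff_threshold if diff_threshold is not None else default_diff_threshold(loop)
        if np.isfinite(thr):
            loop = remove_residual_artifacts(loop, thr, template_half_width)
        u[j] = np.mean(np.abs(loop))
        tau[j] = torque_scale * (np.mean(rec.torque_voltage[s:e]) - baseline)

    if rec.f_stim is None:
        raise ValueError("f_stim unknown")
    return LoopFeatureSeries(
        k=np.arange(len(ranges)),
        u=u,
        tau=tau,
        pw=rec.pulse_widths.copy(),
        f_stim=float(rec.f_stim),
    )
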