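"""End-to-end session orchestration and file formats.

A session is: acquire a recording (simulated or loaded from CSV), reduce it
to per-loop features, identify the torque model on the loops of the
identification phase, free-run predict over the remaining loops with frozen
parameters, and score the prediction.  Phase separation is strict — no
measured torque after the identification boundary influences any predicted
value.

All on-disk artifacts are header-first CSV (or key = value text for
parameter dumps); provenance metadata (seed, rates) travels in ``#``
comment lines above the header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path
from time import perf_counter

import numpy as np
import pandas as pd
import yaml

from festorque import kalman_phm, narx_rnn
from festorque.metrics import PredictionReport
from festorque.muscle_sim import MuscleSimParams, SimulatedSession, simulate_session
from festorque.signal_processing import (
    TORQUE_NM_PER_VOLT,
    LoopFeatureSeries,
    RawRecording,
    compute_loop_features,
    segment_loops,
    smooth_mav,
)
from festorque.stim_protocol import ProtocolConfig, ProtocolSequence, build_session_protocol

log = logging.getLogger("festorque")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionConfig:
    """Flat configuration of a full identify-then-predict session."""

    source: str = "simulate"  # "simulate" | "load"
    recording_path: str = ""
    pulses_path: str = ""
    subject_id: str = "sim"

    f_samp: float = 4096.0
    f_stim: float = 40.0
    id_duration_s: float = 30.0

    estimator: str = "both"  # "kalman" | "narx" | "both"
    l: int = 2
    m: int = 2
    n: int = 2
    lam: float = 0.95
    kalman_mode: str = "joint"  # "joint" | "parameters"
    p0: float = 1.0e3
    normalize_kalman: bool = True
    normalize_narx: bool = False

    blank_window_ms: float = 10.0
    diff_threshold: float | None = None
    template_half_width: int = 2
    # ~0.8 s suits noisy experimental MAV; simulated M-waves are nearly
    # deterministic, so a long window only adds lag that destabilizes
    # free-run prediction.  Raise towards 0.8 for real recordings.
    smooth_window_s: float = 0.2
    torque_scale: float = TORQUE_NM_PER_VOLT

    # protocol (simulate source only)
    pw_max: float = 350.0
    ramp_up_s: float = 0.5
    plateau_s: float = 1.0
    ramp_down_s: float = 0.5
    rest_s: float = 2.0
    pred_cycles: int = 8

    # simulated muscle (simulate source only)
    sim_pw_threshold_us: float = 50.0
    sim_pw_saturation_us: float = 350.0
    sim_mwave_amplitude_mv: float = 1.5
    sim_artifact_amplitude_mv: float = 20.0
    sim_torque_gain_nm: float = 30.0
    sim_natural_freq_hz: float = 1.0
    sim_damping: float = 0.9
    sim_noise_sd_emg_mv: float = 0.02
    sim_noise_sd_torque_nm: float = 0.05
    sim_fatigue_rate_per_min: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("simulate", "load"):
            raise ValueError("source must be 'simulate' or 'load'")
        if self.estimator not in ("kalman", "narx", "both"):
            raise ValueError("estimator must be 'kalman', 'narx' or 'both'")
        n_par = self.l + self.m * self.n + 2
        if not self.id_duration_s * self.f_stim > n_par:
            raise ValueError(
                "id_duration_s too short: identification needs more loops than "
                f"the {n_par} model parameters"
            )
        if not (1.0 <= self.f_stim <= 1000.0):
            raise ValueError("f_stim outside supported range [1, 1000] Hz")

    @property
    def orders(self) -> tuple[int, int, int]:
        return (self.l, self.m, self.n)

    def to_mapping(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SessionConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "SessionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value document")
        return cls.from_mapping(data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)


# --------------------------------------------------------------------------
# CSV artifacts
# --------------------------------------------------------------------------

def _write_csv(path: str | Path, df: pd.DataFrame, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # lossless round-trip


def _read_csv(path: str | Path, required: list[str]) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as dialect error
        raise ValueError(f"unrecognized file dialect in {path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise ValueError(f"format error in {path}: missing column '{col}'")
    return df, meta


def write_recording_csv(
    path: str | Path, pulses_path: str | Path, rec: RawRecording, seed: int | None = None
) -> None:
    t = np.arange(rec.n_samples) / rec.f_samp
    meta = {"f_samp_hz": rec.f_samp}
    if rec.f_stim is not None:
        meta["f_stim_hz"] = rec.f_stim
    if seed is not None:
        meta["seed"] = seed
    _write_csv(path, pd.DataFrame({"time_s": t, "emg_mV": rec.emg, "torque_V": rec.torque_voltage}), meta)
    _write_csv(
        pulses_path,
        pd.DataFrame({"pulse_time_s": rec.pulse_times, "pw_us": rec.pulse_widths}),
        meta,
    )


def read_recording_csv(path: str | Path, pulses_path: str | Path) -> RawRecording:
    df, meta = _read_csv(path, ["time_s", "emg_mV", "torque_V"])
    pdf, _ = _read_csv(pulses_path, ["pulse_time_s", "pw_us"])
    t = df["time_s"].to_numpy()
    f_samp = float(meta.get("f_samp_hz", 1.0 / np.median(np.diff(t))))
    f_stim = float(meta["f_stim_hz"]) if "f_stim_hz" in meta else None
    return RawRecording(
        f_samp=f_samp,
        emg=df["emg_mV"].to_numpy(),
        torque_voltage=df["torque_V"].to_numpy(),
        pulse_times=pdf["pulse_time_s"].to_numpy(),
        pulse_widths=pdf["pw_us"].to_numpy(),
        f_stim=f_stim,
    )


def write_features_csv(path: str | Path, feats: LoopFeatureSeries, seed: int | None = None) -> None:
    meta = {"f_stim_hz": feats.f_stim}
    if seed is not None:
        meta["seed"] = seed
    _write_csv(
        path,
        pd.DataFrame({"k": feats.k, "u_mav_mV": feats.u, "tau_Nm": feats.tau, "pw_us": feats.pw}),
        meta,
    )


def read_features_csv(path: str | Path, f_stim: float | None = None) -> LoopFeatureSeries:
    df, meta = _read_csv(path, ["k", "u_mav_mV", "tau_Nm", "pw_us"])
    if f_stim is None:
        if "f_stim_hz" not in meta:
            raise ValueError("format error: missing column 'f_stim_hz' metadata; pass f_stim")
        f_stim = float(meta["f_stim_hz"])
    return LoopFeatureSeries(
        k=df["k"].to_numpy(dtype=np.int64),
        u=df["u_mav_mV"].to_numpy(),
        tau=df["tau_Nm"].to_numpy(),
        pw=df["pw_us"].to_numpy(),
        f_stim=f_stim,
    )


def write_protocol_csv(path: str | Path, seq: ProtocolSequence, seed: int | None = None) -> None:
    meta = {"f_stim_hz": seq.f_stim}
    if seed is not None:
        meta["seed"] = seed
    _write_csv(
        path,
        pd.DataFrame(
            {
                "loop_k": np.arange(len(seq)),
                "t_s": seq.t,
                "pw_us": seq.pw,
                "cycle_id": seq.cycle_id,
                "phase": seq.phase_label,
            }
        ),
        meta,
    )


def write_ground_truth_csv(path: str | Path, sess: SimulatedSession) -> None:
    _write_csv(
        path,
        pd.DataFrame(
            {
                "k": np.arange(sess.clean_u.size),
                "clean_u": sess.clean_u,
                "clean_tau": sess.clean_tau,
            }
        ),
        {"seed": sess.params.seed},
    )


def write_prediction_csv(
    path: str | Path,
    k: np.ndarray,
    tau_meas: np.ndarray,
    tau_pred: np.ndarray,
    seed: int | None = None,
) -> None:
    meta = {} if seed is None else {"seed": seed}
    _write_csv(
        path,
        pd.DataFrame({"k": k, "tau_Nm": tau_meas, "tau_pred_Nm": tau_pred}),
        meta,
    )


def read_prediction_csv(path: str | Path) -> pd.DataFrame:
    df, _ = _read_csv(path, ["k", "tau_Nm", "tau_pred_Nm"])
    return df


def write_report_csv(path: str | Path, reports: list[PredictionReport], seed: int | None = None) -> None:
    meta = {} if seed is None else {"seed": seed}
    _write_csv(path, pd.DataFrame([r.summary_row() for r in reports]), meta)


def write_params_txt(path: str | Path, params, extra: dict | None = None) -> None:
    """Key-value dump of either estimator's parameters."""
    lines: list[str] = []
    if isinstance(params, kalman_phm.PHMParameters):
        lines.append("estimator = kalman")
        lines += [f"l = {params.l}", f"m = {params.m}", f"n = {params.n}"]
        lines.append("a = " + ",".join(repr(float(v)) for v in params.a))
        lines.append("d = " + ",".join(repr(float(v)) for v in params.d.ravel()))
    elif isinstance(params, narx_rnn.NARXParameters):
        lines.append("estimator = narx")
        lines += [f"l = {params.l}", f"m = {params.m}", f"n = {params.n}", f"k_id = {params.k_id}"]
        lines.append("v = " + ",".join(repr(float(v)) for v in params.v))
        lines.append("w = " + ",".join(repr(float(v)) for v in params.w.ravel()))
        lines.append(f"a = {float(params.a)!r}")
        lines.append(f"b = {float(params.b)!r}")
    else:
        raise TypeError("unsupported parameter object")
    for key, val in (extra or {}).items():
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params_txt(path: str | Path):
    """Inverse of :func:`write_params_txt`; returns the typed parameter object."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    if "estimator" not in kv:
        raise ValueError("unrecognized file dialect: missing 'estimator' key")
    l, m, n = int(kv["l"]), int(kv["m"]), int(kv["n"])
    parse = lambda s: np.array([float(v) for v in s.split(",")])  # noqa: E731
    if kv["estimator"] == "kalman":
        return kalman_phm.PHMParameters(l=l, m=m, n=n, a=parse(kv["a"]), d=parse(kv["d"]).reshape(m, n))
    if kv["estimator"] == "narx":
        return narx_rnn.NARXParameters(
            l=l, m=m, n=n,
            v=parse(kv["v"]),
            w=parse(kv["w"]).reshape(m, n),
            a=float(kv["a"]),
            b=float(kv["b"]),
            k_id=int(kv["k_id"]),
        )
    raise ValueError(f"unrecognized estimator '{kv['estimator']}'")


# --------------------------------------------------------------------------
# session stages
# --------------------------------------------------------------------------

def simulation_inputs(cfg: SessionConfig) -> tuple[ProtocolSequence, MuscleSimParams]:
    """Protocol and muscle parameters implied by a simulate-source config."""
    cycle = cfg.ramp_up_s + cfg.plateau_s + cfg.ramp_down_s + cfg.rest_s
    id_cycles = max(1, int(np.ceil(cfg.id_duration_s / cycle)))
    id_cfg = ProtocolConfig(
        f_stim=cfg.f_stim,
        pw_max=cfg.pw_max,
        ramp_up_s=cfg.ramp_up_s,
        plateau_s=cfg.plateau_s,
        ramp_down_s=cfg.ramp_down_s,
        rest_s=cfg.rest_s,
        n_cycles=id_cycles,
        phase="identification",
        seed=cfg.seed,
    )
    pred_cfg = replace(id_cfg, n_cycles=cfg.pred_cycles, phase="prediction", seed=cfg.seed + 1)
    protocol = build_session_protocol(id_cfg, pred_cfg)
    params = MuscleSimParams(
        pw_threshold_us=cfg.sim_pw_threshold_us,
        pw_saturation_us=cfg.sim_pw_saturation_us,
        mwave_amplitude_mv=cfg.sim_mwave_amplitude_mv,
        artifact_amplitude_mv=cfg.sim_artifact_amplitude_mv,
        torque_gain_nm=cfg.sim_torque_gain_nm,
        natural_freq_hz=cfg.sim_natural_freq_hz,
        damping=cfg.sim_damping,
        noise_sd_emg_mv=cfg.sim_noise_sd_emg_mv,
        noise_sd_torque_nm=cfg.sim_noise_sd_torque_nm,
        fatigue_rate_per_min=cfg.sim_fatigue_rate_per_min,
        seed=cfg.seed,
    )
    return protocol, params


def acquire_recording(cfg: SessionConfig) -> RawRecording:
    if cfg.source == "simulate":
        protocol, params = simulation_inputs(cfg)
        return simulate_session(protocol, params, f_samp=cfg.f_samp).recording
    if not cfg.recording_path or not cfg.pulses_path:
        raise ValueError("source 'load' requires recording_path and pulses_path")
    return read_recording_csv(cfg.recording_path, cfg.pulses_path)


def preprocess(rec: RawRecording, cfg: SessionConfig) -> LoopFeatureSeries:
    """Segment, clean, featurize and smooth a raw recording."""
    ranges = segment_loops(rec)
    feats = compute_loop_features(
        rec,
        ranges,
        blank_window_ms=cfg.blank_window_ms,
        diff_threshold=cfg.diff_threshold,
        template_half_width=cfg.template_half_width,
        torque_scale=cfg.torque_scale,
    )
    u_smooth = smooth_mav(feats.u, cfg.smooth_window_s, feats.f_stim)
    return LoopFeatureSeries(k=feats.k, u=u_smooth, tau=feats.tau, pw=feats.pw, f_stim=feats.f_stim)


def identification_split(feats: LoopFeatureSeries, id_duration_s: float) -> int:
    """Number of identification loops (those starting before the boundary)."""
    n_id = int(np.searchsorted(feats.t, id_duration_s, side="left"))
    if n_id < 1 or n_id >= len(feats):
        raise ValueError("identification boundary leaves an empty phase")
    return n_id


def run_kalman(
    feats: LoopFeatureSeries, n_id: int, cfg: SessionConfig
) -> tuple[PredictionReport, kalman_phm.PHMParameters]:
    u, tau = feats.u, feats.tau
    if cfg.normalize_kalman:
        u_ref = float(np.max(u[:n_id]))
        tau_ref = float(np.max(np.abs(tau[:n_id])))
        if u_ref <= 0 or tau_ref <= 0:
            raise ValueError("kalman: cannot normalize a zero identification record")
    else:
        u_ref = tau_ref = 1.0
    un, taun = u / u_ref, tau / tau_ref

    ident = kalman_phm.kf_identify(
        un[:n_id], taun[:n_id], orders=cfg.orders, lam=cfg.lam,
        mode=cfg.kalman_mode, p0=cfg.p0,
    )
    budget = 1.0 / feats.f_stim
    slow = int(np.sum(ident.per_loop_time_s > budget))
    if slow:
        log.warning("kalman: %d identification loops exceeded the %.1f ms budget", slow, 1e3 * budget)

    pred_n = kalman_phm.kf_free_run_predict(
        un[n_id:],
        ident.params,
        y_init=taun[max(0, n_id - cfg.l) : n_id],
        u_init=un[max(0, n_id - cfg.m) : n_id],
    )
    tau_pred = pred_n * tau_ref
    report = PredictionReport.from_series(
        "kalman", tau[n_id:], tau_pred, k_id=n_id - 1,
        per_loop_time_s=ident.per_loop_time_s, subject_id=cfg.subject_id,
    )
    return report, ident.params


def run_narx(
    feats: LoopFeatureSeries, n_id: int, cfg: SessionConfig
) -> tuple[PredictionReport, narx_rnn.NARXParameters]:
    u, tau = feats.u, feats.tau
    if cfg.normalize_narx:
        u_ref = float(np.max(u[:n_id]))
        tau_ref = float(np.max(np.abs(tau[:n_id])))
        if u_ref <= 0 or tau_ref <= 0:
            raise ValueError("narx: cannot normalize a zero identification record")
    else:
        u_ref = tau_ref = 1.0
    un, taun = u / u_ref, tau / tau_ref

    tic = perf_counter()
    design = narx_rnn.build_design_matrix(un[:n_id], taun[:n_id], orders=cfg.orders)
    params = narx_rnn.identify_narx(design)
    ident_time = perf_counter() - tic
    budget = 1.0 / feats.f_stim
    if ident_time > budget:
        log.warning("narx: one-shot identification took %.1f ms (> %.1f ms loop budget)",
                    1e3 * ident_time, 1e3 * budget)

    pred_n = narx_rnn.narx_free_run_predict(
        un[n_id:],
        params,
        tau_init=taun[max(0, n_id - cfg.l) : n_id],
        u_init=un[max(0, n_id - cfg.m) : n_id],
    )
    tau_pred = pred_n * tau_ref
    report = PredictionReport.from_series(
        "narx", tau[n_id:], tau_pred, k_id=n_id - 1,
        per_loop_time_s=np.array([ident_time]), subject_id=cfg.subject_id,
    )
    return report, params


def run_session(cfg: SessionConfig, out_dir: str | Path | None = None) -> dict[str, PredictionReport]:
    """Full session: acquire, preprocess, identify, predict, evaluate.

    With ``estimator="both"`` both estimators consume the identical feature
    series, enabling a paired comparison.  If ``out_dir`` is given, the
    feature series, parameter dumps, per-estimator prediction CSVs and the
    summary report are written there.
    """
    rec = acquire_recording(cfg)
    feats = preprocess(rec, cfg)
    n_id = identification_split(feats, cfg.id_duration_s)
    log.info("session: %d loops, identification on first %d", len(feats), n_id)

    reports: dict[str, PredictionReport] = {}
    param_objs: dict[str, object] = {}
    if cfg.estimator in ("kalman", "both"):
        reports["kalman"], param_objs["kalman"] = run_kalman(feats, n_id, cfg)
    if cfg.estimator in ("narx", "both"):
        reports["narx"], param_objs["narx"] = run_narx(feats, n_id, cfg)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_features_csv(out / "features.csv", feats, seed=cfg.seed)
        for name, obj in param_objs.items():
            write_params_txt(out / f"params_{name}.txt", obj, extra={"seed": cfg.seed})
        for name, rep in reports.items():
            write_prediction_csv(
                out / f"prediction_{name}.csv",
                feats.k[n_id:], rep.tau_meas, rep.tau_pred, seed=cfg.seed,
            )
        write_report_csv(out / "report.csv", list(reports.values()), seed=cfg.seed)
        cfg.to_file(out / "session_config.yaml")
    return reports
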