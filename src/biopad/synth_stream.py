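"""Seeded synthetic-session generator.

Emulates the forehead pad's signals and the study paradigms so every
pipeline and the wire codec can be exercised without hardware:

* EEG (2 × 400 Hz): pink background noise, a 10 Hz alpha oscillation gated
  by an eyes-open/closed schedule, biphasic ~100 μV blink transients, and a
  50 Hz mains sinusoid;
* EDA (100 Hz): tonic level with slow drift plus bi-exponential
  skin-conductance responses locked to configured stimulus times;
* SKT (100 Hz): stable baseline with a smooth temperature dip during an
  unpleasant-stimulation window;
* PPG (2 × 100 Hz): harmonic pulsatile waveform whose instantaneous rate
  follows a piecewise-linear BPM profile, plus baseline wander and
  accelerometer-coupled motion artifact;
* acceleration (3 × 100 Hz): quiescent noise plus band-limited motion
  bursts with a rhythmic (head-sway) component.

Every generator is a pure function of (config, seed).  Ground truth (blink
times, SCR event times, SKT delta, the instantaneous pulse-rate track,
stimulus times) is returned alongside the signals for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from scipy import signal

from . import packet_codec
from .records import EEG_FS, PERIPHERAL_FS, MultiRateRecord

# ------------------------------------------------------------------ config


@dataclass
class EEGConfig:
    alpha_amp_uv: float = 20.0          # eyes-closed alpha amplitude
    open_alpha_frac: float = 0.05       # residual alpha with eyes open
    alpha_state_schedule: list = field(default_factory=list)  # (t0, t1, state)
    blink_rate_per_min: float = 8.0
    blink_amp_uv: float = 100.0
    mains_amp_uv: float = 10.0
    noise_uv: float = 4.0               # pink-noise RMS


@dataclass
class EDAConfig:
    tonic_us: float = 5.0
    drift_us: float = 0.3               # slow sinusoidal drift amplitude
    noise_us: float = 0.005
    scr_events: list = field(default_factory=list)  # (t, amp_us, rise_s, decay_s)


@dataclass
class SKTConfig:
    baseline_c: float = 34.0
    stim_drop_c: float = 0.2            # magnitude of the dip
    drop_window: tuple | None = None    # (t0, t1) of the smooth transition
    noise_c: float = 0.01


@dataclass
class PPGConfig:
    pr_profile: list = field(default_factory=lambda: [(0.0, 72.0)])  # (t, BPM)
    harmonic_amps: tuple = (1.0, 0.4, 0.15)
    amp_counts: float = 2000.0
    wander_counts: float = 400.0
    artifact_gain: float = 12000.0      # counts per g of filtered acceleration
    motion_amp_suppression: float = 0.6  # pulse shrinkage at full motion


@dataclass
class AccelConfig:
    motion_bursts: list = field(default_factory=list)  # (start_s, dur_s, rms_g)
    quiescent_rms_g: float = 0.02


@dataclass
class SessionConfig:
    duration_s: float = 60.0
    seed: int = 0
    eeg: EEGConfig = field(default_factory=EEGConfig)
    eda: EDAConfig = field(default_factory=EDAConfig)
    skt: SKTConfig = field(default_factory=SKTConfig)
    ppg: PPGConfig = field(default_factory=PPGConfig)
    accel: AccelConfig = field(default_factory=AccelConfig)
    paradigm: list = field(default_factory=list)       # (label, start_s, dur_s)
    stimulus_times_s: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for (t0, t1, state) in self.eeg.alpha_state_schedule:
            if not (0 <= t0 < t1 <= self.duration_s + 1e-9):
                raise ValueError(f"alpha schedule window ({t0}, {t1}) outside session")
            if state not in ("open", "closed"):
                raise ValueError(f"unknown alpha state {state!r}")
        for ev in self.eda.scr_events:
            if not 0 <= ev[0] <= self.duration_s:
                raise ValueError("SCR event outside session")

    def to_yaml(self, path=None) -> str:
        doc = asdict(self)
        doc["eeg"]["alpha_state_schedule"] = [
            list(w) for w in doc["eeg"]["alpha_state_schedule"]]
        doc["skt"]["drop_window"] = (list(doc["skt"]["drop_window"])
                                     if doc["skt"]["drop_window"] else None)
        doc["ppg"]["harmonic_amps"] = list(doc["ppg"]["harmonic_amps"])
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SessionConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        elif "\n" in str(source):
            doc = yaml.safe_load(str(source))
        else:
            with open(source) as f:
                doc = yaml.safe_load(f)
        if not isinstance(doc, dict):
            raise ValueError("malformed session config")
        kwargs = dict(doc)
        for name, sub in (("eeg", EEGConfig), ("eda", EDAConfig),
                          ("skt", SKTConfig), ("ppg", PPGConfig),
                          ("accel", AccelConfig)):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = sub(**kwargs[name])
        if kwargs.get("skt") and kwargs["skt"].drop_window is not None:
            kwargs["skt"].drop_window = tuple(kwargs["skt"].drop_window)
        if kwargs.get("ppg"):
            kwargs["ppg"].harmonic_amps = tuple(kwargs["ppg"].harmonic_amps)
            kwargs["ppg"].pr_profile = [tuple(p) for p in kwargs["ppg"].pr_profile]
        if kwargs.get("eeg"):
            kwargs["eeg"].alpha_state_schedule = [
                tuple(w) for w in kwargs["eeg"].alpha_state_schedule]
        if kwargs.get("eda"):
            kwargs["eda"].scr_events = [tuple(e) for e in kwargs["eda"].scr_events]
        if kwargs.get("accel"):
            kwargs["accel"].motion_bursts = [
                tuple(b) for b in kwargs["accel"].motion_bursts]
        if kwargs.get("paradigm"):
            kwargs["paradigm"] = [tuple(p) for p in kwargs["paradigm"]]
        return cls(**kwargs)


@dataclass
class GroundTruth:
    blink_times_s: np.ndarray
    scr_event_times_s: np.ndarray
    skt_delta_c: float
    pr_track_bpm: np.ndarray          # BPM at 100 Hz
    stimulus_times_s: np.ndarray


# ------------------------------------------------------------- primitives

def _pink_noise(n: int, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise with the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _seed_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(stream,)))


def _blink_kernel(fs: float, amp_uv: float) -> np.ndarray:
    """Biphasic 300 ms transient: one full sine cycle under a Hann taper."""
    n = int(round(0.3 * fs))
    t = np.arange(n) / fs
    return amp_uv * np.sin(2 * np.pi * t / 0.3) * np.hanning(n)


def scr_kernel(t: np.ndarray, amplitude: float, rise_s: float,
               decay_s: float) -> np.ndarray:
    """Bi-exponential SCR shape, peak-normalized to ``amplitude``."""
    if decay_s <= rise_s:
        raise ValueError("decay constant must exceed rise constant")
    g = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return amplitude * g / peak


# ------------------------------------------------------------- generators

def gen_eeg(cfg: SessionConfig, seed: int | None = None):
    """Two-channel 400 Hz EEG; returns (signal (n, 2) μV, blink times)."""
    seed = cfg.seed if seed is None else seed
    e = cfg.eeg
    n = int(round(cfg.duration_s * EEG_FS))
    t = np.arange(n) / EEG_FS

    rng = _seed_for(seed, 1)
    # alpha amplitude envelope from the schedule (default: eyes open)
    amp = np.full(n, e.alpha_amp_uv * e.open_alpha_frac)
    for (t0, t1, state) in e.alpha_state_schedule:
        i0, i1 = int(round(t0 * EEG_FS)), int(round(t1 * EEG_FS))
        amp[i0:i1] = e.alpha_amp_uv if state == "closed" \
            else e.alpha_amp_uv * e.open_alpha_frac
    # 10 Hz carrier with slow frequency jitter (±0.5 Hz random walk)
    jitter = _pink_noise(n, 0.3, rng)
    freq = 10.0 + np.clip(jitter, -0.5, 0.5)
    phase = 2 * np.pi * np.cumsum(freq) / EEG_FS
    alpha = amp * np.sin(phase)

    # blink transients: Poisson arrivals with 1 s dead time
    blink_times = []
    if e.blink_rate_per_min > 0:
        rate = e.blink_rate_per_min / 60.0
        t_next = rng.exponential(1.0 / rate)
        while t_next < cfg.duration_s - 0.35:
            blink_times.append(t_next)
            t_next += 1.0 + rng.exponential(1.0 / rate)
    kernel = _blink_kernel(EEG_FS, e.blink_amp_uv)
    blinks = np.zeros(n)
    for bt in blink_times:
        i0 = int(round(bt * EEG_FS))
        seg = kernel[: n - i0]
        blinks[i0:i0 + len(seg)] += seg

    mains = e.mains_amp_uv * np.sin(2 * np.pi * 50.0 * t)
    channels = []
    for ch, gain in ((0, 1.0), (1, 0.9)):
        noise = _pink_noise(n, e.noise_uv, _seed_for(seed, 10 + ch))
        channels.append(gain * (alpha + blinks) + mains + noise)
    return np.stack(channels, axis=1), np.asarray(blink_times)


def gen_eda(cfg: SessionConfig, seed: int | None = None):
    """100 Hz EDA stream; returns (signal μS, SCR event times)."""
    seed = cfg.seed if seed is None else seed
    e = cfg.eda
    n = int(round(cfg.duration_s * PERIPHERAL_FS))
    t = np.arange(n) / PERIPHERAL_FS
    rng = _seed_for(seed, 2)
    phase0 = rng.uniform(0, 2 * np.pi)
    x = (e.tonic_us
         + e.drift_us * np.sin(2 * np.pi * t / 80.0 + phase0)
         + e.noise_us * rng.standard_normal(n))
    times = []
    for (t0, amp, rise, decay) in e.scr_events:
        times.append(t0)
        if amp == 0:
            continue
        i0 = int(round(t0 * PERIPHERAL_FS))
        tail = t[i0:] - t[i0]
        x[i0:] += scr_kernel(tail, amp, rise, decay)
    return x, np.asarray(times)


def gen_skt(cfg: SessionConfig, seed: int | None = None):
    """100 Hz skin temperature; returns (signal °C, injected delta °C)."""
    seed = cfg.seed if seed is None else seed
    s = cfg.skt
    n = int(round(cfg.duration_s * PERIPHERAL_FS))
    t = np.arange(n) / PERIPHERAL_FS
    rng = _seed_for(seed, 3)
    x = s.baseline_c + s.noise_c * rng.standard_normal(n)
    delta = 0.0
    if s.drop_window is not None and s.stim_drop_c != 0:
        t0, t1 = s.drop_window
        # raised-cosine transition from 0 to -drop between t0 and t1
        ramp = np.zeros(n)
        mid = (t >= t0) & (t <= t1)
        ramp[mid] = 0.5 * (1 - np.cos(np.pi * (t[mid] - t0) / (t1 - t0)))
        ramp[t > t1] = 1.0
        x -= s.stim_drop_c * ramp
        delta = -s.stim_drop_c
    return x, delta


def gen_ppg_accel(cfg: SessionConfig, seed: int | None = None):
    """PPG (n, 2) and acceleration (n, 3) at 100 Hz plus the BPM truth track."""
    seed = cfg.seed if seed is None else seed
    p, a = cfg.ppg, cfg.accel
    n = int(round(cfg.duration_s * PERIPHERAL_FS))
    t = np.arange(n) / PERIPHERAL_FS
    rng = _seed_for(seed, 4)

    prof = np.asarray(p.pr_profile, dtype=float)
    pr_track = np.interp(t, prof[:, 0], prof[:, 1])
    phase = 2 * np.pi * np.cumsum(pr_track / 60.0) / PERIPHERAL_FS
    pulse = sum(h * np.sin((k + 1) * phase)
                for k, h in enumerate(p.harmonic_amps))
    wander = np.sin(2 * np.pi * 0.12 * t + rng.uniform(0, 2 * np.pi))

    accel = a.quiescent_rms_g * rng.standard_normal((n, 3))
    motion_env = np.zeros(n)
    if a.motion_bursts:
        b_lo, a_lo = signal.butter(2, [0.5, 4.0], btype="band",
                                   fs=PERIPHERAL_FS)
        for (start, dur, rms) in a.motion_bursts:
            i0 = int(round(start * PERIPHERAL_FS))
            i1 = min(n, i0 + int(round(dur * PERIPHERAL_FS)))
            if i1 <= i0:
                continue
            m = i1 - i0
            # rhythmic head sway whose tempo drifts across the burst,
            # sweeping through the pulse band — the classic MA confounder
            f0, f1 = sorted(rng.uniform(0.8, 3.2, size=2))
            sway_ph = rng.uniform(0, 2 * np.pi, size=3)
            sway_f = np.linspace(f0, f1, m)
            sway_phase = 2 * np.pi * np.cumsum(sway_f) / PERIPHERAL_FS
            taper = np.hanning(m)
            for axis in range(3):
                rough = signal.lfilter(b_lo, a_lo, rng.standard_normal(m))
                sway = np.sin(sway_phase + sway_ph[axis])
                burst = 0.5 * rough / max(rough.std(), 1e-12) + sway
                accel[i0:i1, axis] += rms * taper * burst / burst.std()
            motion_env[i0:i1] = np.maximum(motion_env[i0:i1], taper)

    # motion artifact: per-axis FIR coupling into the optical path; motion
    # also loosens sensor contact, shrinking the pulsatile component
    fir = rng.normal(0.0, 1.0, size=(3, 5))
    fir /= np.abs(fir).sum(axis=1, keepdims=True)
    artifact = sum(signal.lfilter(fir[axis], 1.0, accel[:, axis])
                   for axis in range(3)) * p.artifact_gain
    pulse = pulse * (1.0 - p.motion_amp_suppression * motion_env)

    ppg = np.empty((n, 2))
    for ch, (gain, dc) in enumerate(((1.0, 0.0), (1.4, 500.0))):
        meas_noise = 20.0 * rng.standard_normal(n)
        ppg[:, ch] = (dc + gain * (p.amp_counts * pulse
                                   + p.wander_counts * wander)
                      + artifact + meas_noise)
    return ppg, accel, pr_track


def gen_session(cfg: SessionConfig):
    """All modalities on a shared clock; returns (record, ground truth)."""
    eeg, blink_times = gen_eeg(cfg)
    eda, scr_times = gen_eda(cfg)
    skt, skt_delta = gen_skt(cfg)
    ppg, accel, pr_track = gen_ppg_accel(cfg)
    record = MultiRateRecord(eeg=eeg, eda=eda, skt=skt, ppg=ppg, accel=accel)
    truth = GroundTruth(
        blink_times_s=blink_times,
        scr_event_times_s=scr_times,
        skt_delta_c=skt_delta,
        pr_track_bpm=pr_track,
        stimulus_times_s=np.asarray(cfg.stimulus_times_s, dtype=float),
    )
    return record, truth


def record_to_packets(record: MultiRateRecord) -> bytes:
    """Quantize a physical-unit record to wire codes and frame it."""
    out = bytearray()
    for i, (eeg_codes, peripheral) in enumerate(
            packet_codec.quantize_record(record)):
        out += packet_codec.encode_frame(eeg_codes, peripheral,
                                         frame_index=i).raw
    return bytes(out)


# ----------------------------------------------------- canonical paradigms

def default_session_config(seed: int = 0) -> SessionConfig:
    """The 6-minute VR paradigm: 30 s rests alternating with 60 s scenes of
    joy, calmness, sadness and fear; pulse rate varies 60–100 BPM; moderate
    head-motion bursts; stimulus-locked SCRs in each scene; SKT dip during
    the sadness scene."""
    scenes = [("rest", 0, 30), ("joy", 30, 60), ("rest", 90, 30),
              ("calmness", 120, 60), ("rest", 180, 30), ("sadness", 210, 60),
              ("rest", 270, 30), ("fear", 300, 60)]
    stimulus_times = [40.0, 65.0, 130.0, 155.0, 220.0, 245.0, 310.0, 335.0]
    rng = np.random.default_rng(seed)
    scr_events = [(t + float(lat), float(amp), 0.75, 3.0)
                  for t, lat, amp in zip(
                      stimulus_times,
                      rng.uniform(1.0, 3.0, len(stimulus_times)),
                      rng.uniform(0.3, 0.8, len(stimulus_times)))]
    bursts = [(40.0, 20.0, 0.5), (100.0, 15.0, 0.4), (135.0, 20.0, 0.5),
              (220.0, 20.0, 0.5), (280.0, 15.0, 0.4), (315.0, 20.0, 0.5)]
    pr_profile = [(0, 70), (30, 72), (60, 85), (90, 78), (120, 68),
                  (180, 72), (210, 80), (240, 88), (270, 76), (300, 95),
                  (330, 100), (360, 82)]
    return SessionConfig(
        duration_s=360.0, seed=seed,
        eeg=EEGConfig(alpha_state_schedule=[(0, 30, "closed")]),
        eda=EDAConfig(scr_events=scr_events),
        skt=SKTConfig(drop_window=(215.0, 262.0)),
        ppg=PPGConfig(pr_profile=pr_profile),
        accel=AccelConfig(motion_bursts=bursts),
        paradigm=scenes, stimulus_times_s=stimulus_times,
    )


def eda_snr_protocol_config(seed: int = 0) -> SessionConfig:
    """150 s quiet-room EDA protocol (4 × 30 s relaxation, 3 × 10 s
    hyperventilation) used for the segmented SNR statistic."""
    scenes = [("relax", 0, 30), ("hyperventilation", 30, 10),
              ("relax", 40, 30), ("hyperventilation", 70, 10),
              ("relax", 80, 30), ("hyperventilation", 110, 10),
              ("relax", 120, 30)]
    return SessionConfig(duration_s=150.0, seed=seed, paradigm=scenes,
                         eeg=EEGConfig(blink_rate_per_min=4.0),
                         ppg=PPGConfig(pr_profile=[(0, 72), (150, 76)]))


def skt_paradigm_config(seed: int = 0) -> SessionConfig:
    """SKT validation paradigm: 20 s baseline, 60 s sadness scene, 90 s rest;
    a 0.2 °C dip develops during the scene."""
    return SessionConfig(
        duration_s=170.0, seed=seed,
        skt=SKTConfig(stim_drop_c=0.2, drop_window=(25.0, 72.0)),
        ppg=PPGConfig(pr_profile=[(0, 70), (170, 74)]),
        paradigm=[("baseline", 0, 20), ("sadness", 20, 60), ("rest", 80, 90)],
    )


def eyes_task_config(seed: int = 0) -> SessionConfig:
    """Eyes-closed / eyes-open task: 15 s clean epochs of each state."""
    return SessionConfig(
        duration_s=30.0, seed=seed,
        eeg=EEGConfig(alpha_state_schedule=[(0, 15, "closed"),
                                            (15, 30, "open")],
                      blink_rate_per_min=0.0),
        ppg=PPGConfig(pr_profile=[(0, 72), (30, 72)]),
    )
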