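"""Synthetic radar and hemodynamic signal generation.

Two generation paths feed the rest of the package:

* a physical FMCW echo simulator (:func:`simulate_radar_cube`) producing
  complex I/Q radar cubes from parametric chest micro-motion, used to
  exercise the DSP front-end against the analytic displacement-to-phase map
  ``4*pi*x/lambda``;
* a hemodynamic generator producing paired (RPW, ABP, SBP, DBP) windows with
  controllable corruption, used to test quality screening and the
  regression model.

Every generator is a pure function of its seed and parameters.  The ABP
waveform model is a per-cycle template: a systolic Gaussian bump, a dicrotic
(second) Gaussian bump and an exponential diastolic tail, normalized per
cycle so the maximum/minimum land exactly on the requested SBP/DBP.  Window
morphology is tied to blood pressure through a smooth invertible map
(:func:`bp_to_morphology`), so that shape alone carries the label — the
property the regression network is asked to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import WindowDataset

C_LIGHT = 299_792_458.0

CORRUPTION_KINDS = ("spike", "drift", "noise_burst", "dropout", "aperiodic")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class RadarConfig:
    """Linear-FMCW chirp parameters (defaults: 77 GHz automotive band,
    3 GHz sweep at 50 MHz/us, 64 fast-time samples at 2 MHz, 4 Rx)."""

    carrier_frequency: float = 77e9        # Hz
    bandwidth: float = 3e9                 # Hz
    chirp_duration: float = 60e-6          # s (ramp time)
    n_chirps: int = 2000
    n_fast_samples: int = 64
    fast_sample_rate: float = 2e6          # Hz
    n_rx: int = 4
    initial_phase: float = 0.0             # rad
    tx_amplitude: float = 1.0
    slow_rate: float = 200.0               # effective chirp (frame) rate, Hz

    def __post_init__(self):
        if self.carrier_frequency <= 0:
            raise ValueError("carrier frequency must be positive")
        for name in ("n_chirps", "n_fast_samples", "n_rx"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def frequency_slope(self) -> float:
        return self.bandwidth / self.chirp_duration  # Hz/s

    @property
    def wavelength(self) -> float:
        return C_LIGHT / self.carrier_frequency

    @property
    def range_resolution(self) -> float:
        """Range covered by one fast-time FFT bin."""
        return C_LIGHT * self.fast_sample_rate / (2 * self.frequency_slope * self.n_fast_samples)


@dataclass
class ChestMotion:
    """Chest-surface displacement sampled at the slow-time (chirp) rate."""

    static_range: float                    # R0, m
    displacement: np.ndarray               # x(t), m
    cardiac: np.ndarray
    respiratory: np.ndarray
    heart_rate: float                      # Hz
    resp_rate: float                       # Hz
    slow_rate: float = 200.0               # Hz

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if np.max(np.abs(self.displacement)) >= self.static_range:
            raise ValueError("|x(t)| must stay below the static range")
        if not np.allclose(self.displacement, self.cardiac + self.respiratory):
            raise ValueError("displacement must equal cardiac + respiratory")


def make_chest_motion(duration: float, heart_rate: float = 1.2,
                      resp_rate: float = 0.25, cardiac_amp: float = 2e-4,
                      resp_amp: float = 1.5e-3, static_range: float = 0.5625,
                      slow_rate: float = 200.0) -> ChestMotion:
    """Sinusoidal cardiac motion (~0.1-0.5 mm) on top of respiratory drift."""
    t = np.arange(int(round(duration * slow_rate))) / slow_rate
    cardiac = cardiac_amp * np.sin(2 * np.pi * heart_rate * t)
    resp = resp_amp * np.sin(2 * np.pi * resp_rate * t)
    return ChestMotion(static_range=static_range, displacement=cardiac + resp,
                       cardiac=cardiac, respiratory=resp, heart_rate=heart_rate,
                       resp_rate=resp_rate, slow_rate=slow_rate)


@dataclass
class HemoParams:
    """Parameters of the per-cycle arterial pulse template."""

    sbp: float                             # mmHg
    dbp: float                             # mmHg
    heart_rate: float                      # Hz
    notch_depth: float = 0.2               # fraction of pulse amplitude
    upstroke_fraction: float = 0.15        # fraction of the cycle
    dicrotic_delay: float = 0.18           # systolic-peak-to-dicrotic-peak, cycle fraction
    decay_tau: float = 0.30                # diastolic decay constant, cycle fraction
    coupling_gain: float = 1.0             # rad per normalized pulse unit
    noise_sd: float = 0.0                  # dimensionless, on the RPW scale

    def __post_init__(self):
        if not (self.sbp > self.dbp > 0):
            raise ValueError("require sbp > dbp > 0")
        if not (0.0 < self.upstroke_fraction < 1.0):
            raise ValueError("upstroke_fraction must lie in (0, 1)")
        if not (0.66 <= self.heart_rate <= 3.0):
            raise ValueError("heart rate outside the physiological band [0.66, 3] Hz")


@dataclass
class CorruptionSpec:
    kind: str
    severity: float                        # [0, 1]

    def __post_init__(self):
        if self.kind not in CORRUPTION_KINDS:
            raise ValueError(f"unknown corruption kind {self.kind!r}; "
                             f"expected one of {CORRUPTION_KINDS}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must lie in [0, 1]")


# ---------------------------------------------------------------------------
# blood-pressure <-> morphology coupling
# ---------------------------------------------------------------------------

SBP_RANGE = (95.0, 165.0)
DBP_RANGE = (55.0, 100.0)
HR_RANGE = (0.8, 1.8)
MIN_PULSE_PRESSURE = 25.0


def bp_to_morphology(sbp: float, dbp: float) -> tuple[float, float, float]:
    """Smooth invertible map from (SBP, DBP) to pulse morphology.

    Higher systolic pressure -> earlier/sharper systolic peak; higher
    diastolic pressure -> a later, shallower dicrotic notch (longer
    systolic-to-dicrotic delay, a pulse-wave-reflection timing effect) and a
    slower diastolic decay (higher peripheral resistance keeps
    end-diastolic pressure up).  This is the "known smooth function" the
    regression model has to invert from waveform shape alone; returns
    (upstroke_fraction, notch_depth, dicrotic_delay, decay_tau).
    """
    upstroke = 0.10 + 0.15 * (SBP_RANGE[1] - sbp) / (SBP_RANGE[1] - SBP_RANGE[0])
    dbp_frac = (dbp - DBP_RANGE[0]) / (DBP_RANGE[1] - DBP_RANGE[0])
    notch = 0.45 - 0.40 * dbp_frac
    delay = 0.10 + 0.18 * dbp_frac
    tau = 0.15 + 0.45 * dbp_frac
    return (float(np.clip(upstroke, 0.06, 0.35)),
            float(np.clip(notch, 0.02, 0.5)),
            float(np.clip(delay, 0.08, 0.30)),
            float(np.clip(tau, 0.10, 0.65)))


# ---------------------------------------------------------------------------
# waveform generation
# ---------------------------------------------------------------------------

def _cycle_shape(u: np.ndarray, params: HemoParams) -> np.ndarray:
    """Dimensionless pulse template evaluated at cycle phase u in [0, 1)."""
    u1 = params.upstroke_fraction
    s1 = 0.55 * u1
    u2 = min(u1 + params.dicrotic_delay, 0.70)
    s2 = 0.045
    a2 = np.clip(0.65 - params.notch_depth, 0.15, 0.9)
    tail = np.where(u > u2, 0.30 * np.exp(-(u - u2) / params.decay_tau), 0.0)
    return (np.exp(-0.5 * ((u - u1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((u - u2) / s2) ** 2)
            + tail)


def generate_abp_waveform(params: HemoParams, length: int, fs: float,
                          rng_seed: int = 0) -> np.ndarray:
    """Arterial-pressure waveform in mmHg with per-cycle SBP/DBP anchoring.

    The per-cycle shape is normalized on a dense phase grid, so every full
    cardiac cycle attains max ~= sbp and min ~= dbp (within sampling error,
    < 1 mmHg at 100 Hz) before noise.
    """
    if length < fs / params.heart_rate:
        raise ValueError("window must cover at least one full cardiac cycle")
    rng = np.random.default_rng(rng_seed)
    grid = np.linspace(0.0, 1.0, 2048, endpoint=False)
    shape_grid = _cycle_shape(grid, params)
    lo, hi = shape_grid.min(), shape_grid.max()
    t = np.arange(length) / fs
    phase0 = rng.uniform(0.0, 1.0)
    u = np.mod(params.heart_rate * t + phase0, 1.0)
    s = (_cycle_shape(u, params) - lo) / (hi - lo)
    abp = params.dbp + (params.sbp - params.dbp) * s
    if params.noise_sd > 0:
        abp = abp + rng.normal(0.0, params.noise_sd * (params.sbp - params.dbp),
                               size=length)
    return abp


def derive_rpw_from_abp(abp: np.ndarray, params: HemoParams, rng_seed: int = 0,
                        fs: float = 100.0, smooth_hz: float | None = 12.0) -> np.ndarray:
    """Dimensionless radar pulse wave coupled to the ABP waveform.

    The chest-displacement phase tracks the pressure pulse: the ABP is
    amplitude-normalized, low-pass smoothed (zero phase, so peak/notch
    timing is preserved) and scaled by the displacement-phase coupling gain,
    then additive Gaussian sensor noise of sd ``params.noise_sd`` is applied.
    Pass ``smooth_hz=None`` for identity smoothing.
    """
    abp = np.asarray(abp, dtype=np.float64)
    if not np.all(np.isfinite(abp)):
        raise ValueError("ABP waveform must be finite")
    rng = np.random.default_rng(rng_seed)
    sd = abp.std()
    norm = (abp - abp.mean()) / (sd + 1e-12) if sd > 0 else np.zeros_like(abp)
    if smooth_hz is not None and sd > 0:
        sos = signal.butter(4, smooth_hz / (fs / 2), btype="low", output="sos")
        norm = signal.sosfiltfilt(sos, norm)
    rpw = params.coupling_gain * norm
    if params.noise_sd > 0:
        rpw = rpw + rng.normal(0.0, params.noise_sd, size=rpw.shape)
    return rpw


# ---------------------------------------------------------------------------
# FMCW echo simulation
# ---------------------------------------------------------------------------

def simulate_radar_cube(motion: ChestMotion, cfg: RadarConfig,
                        clutter_amp: float = 0.0,
                        dc_offset: complex | np.ndarray = 0.0,
                        rng_seed: int = 0, target_angle: float = 0.0,
                        noise_sd: float = 0.0,
                        clutter_range: float | None = None) -> np.ndarray:
    """Complex I/Q cube (chirps M x fast-time N x channels) for one target.

    Per chirp m the chest contributes an IF tone at the beat frequency of
    R(t_m) = R0 + x(t_m), with slow-time phase 4*pi*R(t_m)/lambda; a uniform
    linear array with half-wavelength spacing imposes the geometric phase
    exp(-j*2*pi*d*n*sin(theta)/lambda) on channel n.  A stationary reflector
    of amplitude ``clutter_amp`` adds a chirp-invariant component, plus
    per-channel complex DC offsets and optional receiver noise.
    """
    M = cfg.n_chirps
    if len(motion.displacement) < M:
        raise ValueError(f"motion provides {len(motion.displacement)} samples, "
                         f"need {M} chirps")
    rng = np.random.default_rng(rng_seed)
    lam = cfg.wavelength
    slope = cfg.frequency_slope
    t_fast = np.arange(cfg.n_fast_samples) / cfg.fast_sample_rate
    R = motion.static_range + motion.displacement[:M]
    f_beat = 2.0 * slope * R / C_LIGHT                          # (M,)
    psi = 4.0 * np.pi * R / lam + cfg.initial_phase             # (M,)
    d = lam / 2.0
    chan = np.arange(cfg.n_rx)
    chi = -2.0 * np.pi * d * chan * np.sin(target_angle) / lam  # (n_rx,)
    cube = cfg.tx_amplitude * np.exp(1j * (
        2.0 * np.pi * f_beat[:, None, None] * t_fast[None, :, None]
        + psi[:, None, None] + chi[None, None, :]))
    if clutter_amp:
        Rc = motion.static_range + 0.28 if clutter_range is None else clutter_range
        fb_c = 2.0 * slope * Rc / C_LIGHT
        psi_c = 4.0 * np.pi * Rc / lam
        cube = cube + clutter_amp * np.exp(
            1j * (2.0 * np.pi * fb_c * t_fast + psi_c))[None, :, None]
    dc = np.broadcast_to(np.asarray(dc_offset, dtype=np.complex128), (cfg.n_rx,))
    cube = cube + dc[None, None, :]
    if noise_sd > 0:
        cube = cube + noise_sd * (rng.standard_normal(cube.shape)
                                  + 1j * rng.standard_normal(cube.shape)) / np.sqrt(2)
    return cube


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def inject_corruption(segment: np.ndarray, spec: CorruptionSpec,
                      rng_seed: int = 0) -> tuple[np.ndarray, int]:
    """Apply one named distortion; returns (signal, label) with label 1 when
    corrupted.  ``severity=0`` is an exact identity with a clean label."""
    x = np.asarray(segment, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("segment must be finite")
    if spec.severity == 0.0:
        return x.copy(), 0
    rng = np.random.default_rng(rng_seed)
    n = len(x)
    sd = x.std() if x.std() > 0 else 1.0
    out = x.copy()
    sev = spec.severity
    if spec.kind == "spike":
        k = 1 + int(round(4 * sev))
        idx = rng.choice(n, size=min(k, n), replace=False)
        amps = sd * (5.0 + 5.0 * rng.random(len(idx))) * sev
        out[idx] += amps * rng.choice([-1.0, 1.0], size=len(idx))
    elif spec.kind == "drift":
        t = np.arange(n) / n
        ramp = rng.uniform(-1, 1) * t
        wave = np.sin(2 * np.pi * rng.uniform(1.0, 3.0) * t + rng.uniform(0, 2 * np.pi))
        out += 4.0 * sd * sev * (0.5 * ramp + 0.5 * wave)
    elif spec.kind == "noise_burst":
        span = max(1, int(round(n * (0.1 + 0.2 * sev))))
        start = rng.integers(0, n - span + 1)
        out[start:start + span] += rng.normal(0.0, 4.0 * sd * sev, size=span)
    elif spec.kind == "dropout":
        span = max(1, int(round(n * 0.3 * sev)))
        start = rng.integers(0, n - span + 1)
        out[start:start + span] = 0.0
    elif spec.kind == "aperiodic":
        spec_x = np.fft.rfft(x)
        phases = rng.uniform(0, 2 * np.pi, size=len(spec_x))
        phases[0] = 0.0
        scrambled = np.fft.irfft(np.abs(spec_x) * np.exp(1j * phases), n=n)
        out = (1.0 - sev) * x + sev * scrambled
    return out, 1


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    """Study conditions for the synthetic cohort."""

    window_len: int = 1000
    fs: float = 100.0
    bp_modulation_mmhg: float = 10.0       # within-subject slow BP swing
    hr_jitter: float = 0.03                # Hz, per-window
    rpw_noise_sd: float = 0.02
    label_noise_sd: float = 0.0            # mmHg, observational noise on labels
    severity_range: tuple[float, float] = (0.5, 1.0)
    kinds: tuple[str, ...] = CORRUPTION_KINDS


def make_dataset(n_subjects: int, windows_per_subject: int,
                 corrupt_fraction: float = 0.0, rng_seed: int = 0,
                 spec: DatasetSpec | None = None) -> WindowDataset:
    """Synthetic cohort of paired (RPW, ABP, SBP, DBP) windows.

    Per subject, baseline SBP ~ U[95, 165] mmHg and DBP ~ U[55, 100] mmHg
    with pulse pressure >= 25 mmHg, heart rate ~ U[0.8, 1.8] Hz; within a
    session (SBP, DBP) are modulated by a slow +-10 mmHg sinusoid so
    within-subject correlation is meaningful.  Exactly
    ``round(corrupt_fraction * total)`` windows receive a corruption of
    random kind at a severity drawn from ``spec.severity_range``.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for subject-wise splits")
    if not (0.0 <= corrupt_fraction <= 1.0):
        raise ValueError("corrupt_fraction must lie in [0, 1]")
    spec = spec or DatasetSpec()
    rng = np.random.default_rng(rng_seed)
    L, fs = spec.window_len, spec.fs
    total = n_subjects * windows_per_subject

    rpw = np.empty((total, L))
    abp = np.empty((total, L))
    sbp = np.empty(total)
    dbp = np.empty(total)
    subject = np.empty(total, dtype=np.int64)
    corrupt = np.zeros(total, dtype=np.uint8)

    i = 0
    for sid in range(n_subjects):
        base_sbp = rng.uniform(*SBP_RANGE)
        base_dbp = rng.uniform(*DBP_RANGE)
        while base_sbp - base_dbp < MIN_PULSE_PRESSURE + 5.0:
            base_dbp = rng.uniform(*DBP_RANGE)
        base_hr = rng.uniform(*HR_RANGE)
        # independent modulation phases: systolic and diastolic pressure
        # drift on their own schedules within a session, so neither target
        # is a within-subject affine function of the other
        phase_sys = rng.uniform(0, 2 * np.pi)
        phase_dia = rng.uniform(0, 2 * np.pi)
        for w in range(windows_per_subject):
            cyc = 2 * np.pi * w / max(windows_per_subject, 1)
            sbp_w = float(np.clip(
                base_sbp + spec.bp_modulation_mmhg * np.sin(cyc + phase_sys),
                *SBP_RANGE))
            dbp_w = float(np.clip(
                base_dbp + 0.6 * spec.bp_modulation_mmhg * np.sin(cyc + phase_dia),
                *DBP_RANGE))
            hr_w = float(np.clip(base_hr + rng.normal(0, spec.hr_jitter), *HR_RANGE))
            upstroke, notch, delay, tau = bp_to_morphology(sbp_w, dbp_w)
            params = HemoParams(sbp=sbp_w, dbp=dbp_w, heart_rate=hr_w,
                                notch_depth=notch, upstroke_fraction=upstroke,
                                dicrotic_delay=delay, decay_tau=tau,
                                noise_sd=spec.rpw_noise_sd)
            seed_w = int(rng.integers(0, 2**31 - 1))
            abp_w = generate_abp_waveform(params, L, fs, rng_seed=seed_w)
            rpw_w = derive_rpw_from_abp(abp_w, params, rng_seed=seed_w + 1, fs=fs)
            abp[i] = abp_w
            rpw[i] = rpw_w
            sbp[i] = sbp_w + (rng.normal(0, spec.label_noise_sd)
                              if spec.label_noise_sd > 0 else 0.0)
            dbp[i] = dbp_w + (rng.normal(0, spec.label_noise_sd)
                              if spec.label_noise_sd > 0 else 0.0)
            subject[i] = sid
            i += 1

    n_corrupt = int(round(corrupt_fraction * total))
    if n_corrupt:
        picked = rng.choice(total, size=n_corrupt, replace=False)
        for j in picked:
            kind = spec.kinds[rng.integers(0, len(spec.kinds))]
            sev = float(rng.uniform(*spec.severity_range))
            rpw[j], corrupt[j] = inject_corruption(
                rpw[j], CorruptionSpec(kind=kind, severity=sev),
                rng_seed=int(rng.integers(0, 2**31 - 1)))
    return WindowDataset(rpw=rpw, abp=abp, sbp=sbp, dbp=dbp, subject=subject,
                         corrupt=corrupt, fs=fs)
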