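"""Synthetic FCCW bioradar scene simulator.

Generates labelled measurements with the physical structure the detection
pipeline assumes: sinusoidal chest displacement, two-way Doppler phase
modulation of each comb tone, multipath echoes landing in distinct range
bins with individual motion couplings, static clutter, slow drift confined
below the analysis band, additive complex noise, and optional short
transient disturbances mid-measurement.

Conventions
-----------
* A measurement is a complex tone-by-slow-time matrix ``[n_tones, n_samples]``.
* A path at range bin ``r`` contributes the linear tone phase
  ``exp(-j 2 pi i r / N)`` on tone ``i``, so a unitary inverse DFT across
  tones concentrates it in range bin ``r``.
* Chest motion modulates the path phase by ``(4 pi / lambda_i) * coupling *
  x(t)`` with the per-tone wavelength ``lambda_i = c / f_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

WITH_PERSON = "with_person"
WITHOUT_PERSON = "without_person"

#: analysis band for respiration, Hz
BAND = (0.08, 1.0)

BODY_POSITIONS = ("sitting", "right_lateral", "left_lateral", "supine", "prone")
#: empirical sampling proportions of the body positions
BODY_POSITION_WEIGHTS = (0.20, 0.10, 0.10, 0.40, 0.20)


@dataclass(frozen=True)
class ChestMotionParams:
    """Sinusoidal chest-wall displacement x(t) = x_max sin(2 pi f_resp t + phase0).

    Parameters
    ----------
    x_max : float
        Displacement amplitude in metres (typically a few millimetres).
    f_resp : float
        Respiratory rate in Hz; resting adults breathe at roughly
        0.15-0.5 Hz, the analysis band is [0.08, 1] Hz.
    phase0 : float
        Initial phase in radians.
    """

    x_max: float
    f_resp: float
    phase0: float = 0.0
    #: fractional slow wander of the instantaneous rate (human breathing is
    #: not strictly constant); 0 gives the pure sinusoid
    rate_variability: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x_max", "f_resp", "phase0", "rate_variability"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite motion parameter {name!r}")
        if self.x_max < 0:
            raise ValueError("x_max must be >= 0")
        if self.rate_variability < 0:
            raise ValueError("rate_variability must be >= 0")


@dataclass(frozen=True)
class MotionTrace:
    """Chest displacement, velocity and instantaneous Doppler frequency."""

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    f_D: np.ndarray


@dataclass(frozen=True)
class RadarConfig:
    """FCCW radar front-end parameters.

    The comb has ``n_tones`` tones spanning bandwidth ``BW`` centred on
    ``carrier``.  ``fs`` is the slow-time sampling rate: the rate at which
    the whole comb is sampled, i.e. the rate at which vital-sign modulation
    is observed.
    """

    n_tones: int = 32
    carrier: float = 1.3e9
    BW: float = 60e6
    c: float = 299792458.0
    fs: float = 20.0

    def __post_init__(self) -> None:
        if self.n_tones < 2:
            raise ValueError("n_tones must be >= 2")
        if self.BW <= 0:
            raise ValueError("BW must be > 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength in metres."""
        return self.c / self.carrier

    @property
    def tone_frequencies(self) -> np.ndarray:
        """RF frequency of each comb tone, Hz."""
        i = np.arange(self.n_tones)
        return self.carrier - self.BW / 2 + i * self.BW / (self.n_tones - 1)

    @property
    def range_resolution(self) -> float:
        """Range bin extent c / (2 BW), metres."""
        return self.c / (2.0 * self.BW)


@dataclass(frozen=True)
class MultipathComponent:
    """One propagation path: range bin, reflectivity and motion coupling.

    ``coupling`` in [-1, 1] projects the chest displacement onto the path
    direction; 0 means the motion is perpendicular to the arriving wave and
    leaves the echo unmodulated.
    """

    range_bin: int
    amplitude: float
    coupling: float = 1.0

    def __post_init__(self) -> None:
        if self.range_bin < 0:
            raise ValueError("range_bin must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [-1, 1]")


@dataclass(frozen=True)
class Disturbance:
    """Short transient perturbation applied to selected range bins.

    Modelled as an additive complex transient with a raised-cosine envelope,
    mimicking jump discontinuities caused by brief body movement.
    """

    start: float
    duration: float
    amplitude: float
    range_bins: tuple[int, ...] = (1, 2)
    phase: float = 0.0


@dataclass(frozen=True)
class Interference:
    """Stationary narrowband clutter from a periodic non-respiratory source.

    Machinery, building vibration or swaying structures produce stable
    spectral lines inside the analysis band, typically faster than resting
    breathing.  Modelled as a constant-envelope tone with slow phase noise.
    """

    range_bin: int
    amplitude: float
    freq: float
    phase0: float = 0.0
    phase_noise: float = 0.05  # rad per sample random-walk step


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one simulated measurement scene."""

    label: str
    paths: tuple[MultipathComponent, ...] = ()
    motion: ChestMotionParams | None = None
    clutter_amplitudes: tuple[float, ...] = ()
    drift: float = 0.0
    noise_sigma: float = 0.0
    disturbance: Disturbance | None = None
    interference: tuple[Interference, ...] = ()
    T_meas: float = 60.0
    body_position: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (WITH_PERSON, WITHOUT_PERSON):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == WITH_PERSON and self.motion is None:
            raise ValueError("with_person scene requires chest motion")
        if self.label == WITHOUT_PERSON and self.motion is not None:
            raise ValueError("without_person scene must not carry chest motion")
        if self.T_meas <= 0:
            raise ValueError("T_meas must be > 0")


@dataclass
class FCCWMeasurement:
    """Raw unit of analysis: complex tone-by-slow-time matrix plus metadata."""

    tones: np.ndarray
    fs: float
    T_meas: float
    label: str
    metadata: dict = field(default_factory=dict)

    @property
    def n_tones(self) -> int:
        return self.tones.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tones.shape[1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def simulate_chest_motion(
    motion: ChestMotionParams, t_grid: np.ndarray, radar: RadarConfig
) -> MotionTrace:
    """Evaluate displacement, velocity and Doppler frequency analytically.

    x(t) = x_max sin(2 pi f t + p0)
    v(t) = 2 pi f x_max cos(2 pi f t + p0)
    f_D(t) = (2 / lambda) v(t), two-way Doppler at the carrier wavelength.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    w = 2 * np.pi * motion.f_resp
    x = motion.x_max * np.sin(w * t + motion.phase0)
    v = motion.x_max * w * np.cos(w * t + motion.phase0)
    f_D = (2.0 / radar.wavelength) * v
    return MotionTrace(t=t, x=x, v=v, f_D=f_D)


def _drift_series(n: int, fs: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Complex random-walk drift low-passed below 0.04 Hz, unit-RMS scaled."""
    if amplitude == 0.0 or n < 2:
        return np.zeros(n, dtype=complex)
    walk = np.cumsum(rng.standard_normal(n) + 1j * rng.standard_normal(n))
    cutoff = min(0.04, 0.45 * fs)
    sos = _sig.butter(2, cutoff, btype="low", fs=fs, output="sos")
    drift = _sig.sosfiltfilt(sos, walk.real) + 1j * _sig.sosfiltfilt(sos, walk.imag)
    drift -= drift.mean()
    rms = np.sqrt(np.mean(np.abs(drift) ** 2))
    if rms > 0:
        drift /= rms
    return amplitude * drift


def _disturbance_envelope(t: np.ndarray, d: Disturbance) -> np.ndarray:
    """Raised-cosine window of the transient, zero outside [start, start+duration]."""
    env = np.zeros_like(t)
    inside = (t >= d.start) & (t <= d.start + d.duration)
    phase = (t[inside] - d.start) / d.duration
    env[inside] = 0.5 * (1 - np.cos(2 * np.pi * phase))
    return env


def simulate_measurement(
    scene: SceneConfig, radar: RadarConfig | None = None, seed: int = 0
) -> FCCWMeasurement:
    """Synthesize the complex tone matrix of one scene.

    Each multipath component ``p`` contributes, on tone ``i``,

        amplitude_p * exp(-j 2 pi i r_p / N) * exp(j (4 pi / lambda_i) coupling_p x(t))

    plus static clutter per range bin, additive low-frequency drift,
    transient disturbances on selected bins, and complex white noise.
    Deterministic for a given ``(scene, radar, seed)``.
    """
    radar = radar or RadarConfig()
    for p in scene.paths:
        if p.range_bin >= radar.n_tones // 2:
            raise ValueError(
                f"range_bin {p.range_bin} unresolvable with {radar.n_tones} tones"
            )
    rng = np.random.default_rng(seed)
    n_samples = int(round(radar.fs * scene.T_meas))
    t = np.arange(n_samples) / radar.fs
    n = radar.n_tones
    i = np.arange(n)
    lambdas = radar.c / radar.tone_frequencies

    if scene.motion is not None:
        mo = scene.motion
        if mo.rate_variability > 0 and n_samples > 1:
            # instantaneous rate wanders slowly around f_resp; displacement
            # follows the integrated phase
            walk = np.cumsum(rng.standard_normal(n_samples))
            sos = _sig.butter(2, min(0.03, 0.45 * radar.fs), btype="low",
                              fs=radar.fs, output="sos")
            wander = _sig.sosfiltfilt(sos, walk)
            wander -= wander.mean()
            rms = np.sqrt(np.mean(wander**2))
            if rms > 0:
                wander /= rms
            f_inst = mo.f_resp * (1.0 + mo.rate_variability * wander)
            phase = 2 * np.pi * np.cumsum(f_inst) / radar.fs + mo.phase0
            x = mo.x_max * np.sin(phase)
        else:
            x = simulate_chest_motion(mo, t, radar).x
    else:
        x = np.zeros(n_samples)

    # per-range-bin baseband content shared by all tones
    bins: dict[int, np.ndarray] = {}

    def _bin(r: int) -> np.ndarray:
        if r not in bins:
            bins[r] = np.zeros(n_samples, dtype=complex)
        return bins[r]

    for r, amp in enumerate(scene.clutter_amplitudes):
        if amp:
            _bin(r)[:] += amp
    if scene.drift:
        # drift is slow variation of the static reflections, so its level
        # follows each bin's clutter strength (strongest at near range)
        for r, amp in enumerate(scene.clutter_amplitudes):
            if amp:
                _bin(r)[:] += _drift_series(n_samples, radar.fs, scene.drift * amp, rng)
    if scene.disturbance is not None:
        env = _disturbance_envelope(t, scene.disturbance)
        burst = scene.disturbance.amplitude * env * np.exp(1j * scene.disturbance.phase)
        for r in scene.disturbance.range_bins:
            _bin(int(r))[:] += burst
    for itf in scene.interference:
        phase_walk = np.cumsum(rng.standard_normal(n_samples)) * itf.phase_noise
        _bin(itf.range_bin)[:] += itf.amplitude * np.exp(
            1j * (2 * np.pi * itf.freq * t + itf.phase0 + phase_walk)
        )

    tones = np.zeros((n, n_samples), dtype=complex)
    for r, series in bins.items():
        tones += np.exp(-2j * np.pi * i[:, None] * r / n) * series[None, :]
    for p in scene.paths:
        steer = np.exp(-2j * np.pi * i * p.range_bin / n)
        if scene.motion is not None and p.coupling != 0.0:
            phase = (4 * np.pi / lambdas)[:, None] * (p.coupling * x)[None, :]
            tones += p.amplitude * steer[:, None] * np.exp(1j * phase)
        else:
            tones += p.amplitude * steer[:, None]
    if scene.noise_sigma > 0:
        noise = rng.standard_normal((n, n_samples)) + 1j * rng.standard_normal((n, n_samples))
        tones += scene.noise_sigma / np.sqrt(2) * noise

    meta = {
        "seed": seed,
        "body_position": scene.body_position,
        "f_resp": scene.motion.f_resp if scene.motion else None,
    }
    return FCCWMeasurement(
        tones=tones.astype(np.complex64), fs=radar.fs, T_meas=scene.T_meas,
        label=scene.label, metadata=meta,
    )


@dataclass(frozen=True)
class SceneSampler:
    """Randomized scene-parameter distributions for dataset generation.

    Defaults emulate a laboratory rubble scenario: echoes in the first five
    range bins with decaying strength, most with-person bins coupled to the
    chest motion but some nearly perpendicular, clutter everywhere, drift
    and noise of variable level, and occasional brief disturbances.
    """

    n_ranges: int = 5
    f_resp_range: tuple[float, float] = (0.15, 0.4)
    rate_variability_range: tuple[float, float] = (0.02, 0.12)
    x_max_range: tuple[float, float] = (0.003, 0.009)
    coupling_range: tuple[float, float] = (0.4, 1.0)
    p_uncoupled: float = 0.06
    amplitude_range: tuple[float, float] = (0.25, 1.2)
    range_decay: float = 0.3
    clutter_range: tuple[float, float] = (0.1, 0.6)
    near_range_clutter_boost: float = 3.0
    drift_range: tuple[float, float] = (0.1, 0.7)
    noise_sigma_range: tuple[float, float] = (0.04, 0.18)
    p_disturbance: float = 0.4
    disturbance_amplitude_range: tuple[float, float] = (0.4, 1.2)
    p_interference: float = 0.35
    p_interference_occupied: float = 0.12
    interference_freq_range: tuple[float, float] = (0.5, 1.0)
    interference_amplitude_range: tuple[float, float] = (0.15, 0.5)
    T_meas: float = 60.0


def sample_scene(
    label: str, sampler: SceneSampler | None = None, rng: np.random.Generator | None = None
) -> SceneConfig:
    """Draw one random SceneConfig of the requested class."""
    sampler = sampler or SceneSampler()
    rng = rng if rng is not None else np.random.default_rng()
    u = lambda lo_hi: rng.uniform(*lo_hi)

    motion = None
    paths = []
    if label == WITH_PERSON:
        motion = ChestMotionParams(
            x_max=u(sampler.x_max_range),
            f_resp=u(sampler.f_resp_range),
            phase0=rng.uniform(0, 2 * np.pi),
            rate_variability=u(sampler.rate_variability_range),
        )
        for r in range(1, sampler.n_ranges + 1):
            if rng.uniform() < sampler.p_uncoupled:
                coupling = rng.uniform(-0.05, 0.05)
            else:
                coupling = u(sampler.coupling_range) * rng.choice([-1.0, 1.0])
            amp = u(sampler.amplitude_range) * np.exp(-sampler.range_decay * (r - 1))
            paths.append(MultipathComponent(range_bin=r, amplitude=amp, coupling=coupling))
    clutter = np.zeros(sampler.n_ranges + 1)
    clutter[1:] = rng.uniform(*sampler.clutter_range, size=sampler.n_ranges)
    clutter[1] *= sampler.near_range_clutter_boost  # direct-leakage residue
    if label == WITHOUT_PERSON:
        # empty scene: stronger static clutter stands in for the bare set-up
        clutter[1:] *= 2.0

    disturbance = None
    if rng.uniform() < sampler.p_disturbance:
        n_bins = rng.integers(1, sampler.n_ranges + 1)
        bins = tuple(int(b) for b in rng.choice(
            np.arange(1, sampler.n_ranges + 1), size=n_bins, replace=False))
        start = rng.uniform(0.3 * sampler.T_meas, 0.6 * sampler.T_meas)
        disturbance = Disturbance(
            start=start,
            duration=rng.uniform(2.0, 8.0),
            amplitude=u(sampler.disturbance_amplitude_range),
            range_bins=bins,
            phase=rng.uniform(0, 2 * np.pi),
        )

    interference = ()
    p_itf = sampler.p_interference_occupied if label == WITH_PERSON else sampler.p_interference
    if rng.uniform() < p_itf:
        interference = (
            Interference(
                range_bin=int(rng.integers(1, sampler.n_ranges + 1)),
                amplitude=u(sampler.interference_amplitude_range),
                freq=u(sampler.interference_freq_range),
                phase0=rng.uniform(0, 2 * np.pi),
            ),
        )

    return SceneConfig(
        label=label,
        motion=motion,
        interference=interference,
        paths=tuple(paths),
        clutter_amplitudes=tuple(clutter),
        drift=u(sampler.drift_range),
        noise_sigma=u(sampler.noise_sigma_range),
        disturbance=disturbance,
        T_meas=sampler.T_meas,
        body_position=str(rng.choice(BODY_POSITIONS, p=BODY_POSITION_WEIGHTS))
        if label == WITH_PERSON
        else None,
    )


def generate_dataset(
    n_with: int,
    n_without: int,
    ranges_per_measurement: int = 5,
    sampler: SceneSampler | None = None,
    radar: RadarConfig | None = None,
    seed: int = 0,
) -> tuple[list[FCCWMeasurement], "pandas.DataFrame"]:
    """Generate a labelled collection of measurements plus a manifest.

    Returns ``(measurements, manifest)`` where the manifest is one row per
    measurement recording the scene parameters for parameter-recovery tests.
    Each measurement later yields ``ranges_per_measurement`` observations, so
    the observation count is ``(n_with + n_without) * ranges_per_measurement``.
    """
    import pandas as pd

    if n_with <= 0 or n_without <= 0:
        raise ValueError("counts must be > 0")
    radar = radar or RadarConfig()
    sampler = sampler or SceneSampler(n_ranges=ranges_per_measurement)
    if ranges_per_measurement > radar.n_tones // 2:
        raise ValueError("ranges_per_measurement exceeds n_tones/2")
    root = np.random.default_rng(seed)
    measurements: list[FCCWMeasurement] = []
    rows = []
    labels = [WITH_PERSON] * n_with + [WITHOUT_PERSON] * n_without
    for k, label in enumerate(labels):
        scene_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        scene = sample_scene(label, sampler, scene_rng)
        m_seed = int(root.integers(0, 2**31 - 1))
        m = simulate_measurement(scene, radar, seed=m_seed)
        mid = f"m{k:05d}"
        m.metadata["measurement_id"] = mid
        measurements.append(m)
        rows.append(
            {
                "measurement_id": mid,
                "label": label,
                "body_position": scene.body_position,
                "f_resp": scene.motion.f_resp if scene.motion else np.nan,
                "x_max": scene.motion.x_max if scene.motion else np.nan,
                "drift": scene.drift,
                "noise_sigma": scene.noise_sigma,
                "has_disturbance": scene.disturbance is not None,
                "n_ranges": ranges_per_measurement,
                "seed": m_seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.attrs["n_observations"] = len(measurements) * ranges_per_measurement
    return measurements, manifest
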