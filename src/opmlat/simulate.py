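"""Synthetic trial-epoched recordings.

Each trial holds a rest period followed by a task period during which the
beta-band source amplitude drops.  Sensor data are the sum of

* the projected source signal (band-limited Gaussian noise with a
  task-locked amplitude envelope),
* environmental interference: shared spatial mixtures of a small basis of
  time series (slow drifts plus 50 Hz and 77 Hz lines) appearing in both
  scalp and reference channels, and
* independent white sensor noise.

With the default rank-4 basis the interference in the scalp channels lies
exactly in the span of the reference channels when sensor noise is zero,
which makes reference regression exact — the well-specified regime the
preprocessing tests exploit.

The source waveform is stochastic (band-limited noise), not a deterministic
oscillation: the downstream analysis measures power changes, not
phase-locked responses.  Default amplitudes are artifact-chosen so that the
sensor-level percent change lands in the tens-of-percent range; no
signal-to-noise figure is available to pin them further.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import signal

from ._exceptions import ConfigurationError, ValidationError
from .dataset import DYNAMIC_RANGE_T, TrialDataset
from .forward import LeadFieldSet, point_leadfield
from .geometry import SensorArray

#: MNI coordinate of the default (left inferior frontal) source, mm
DEFAULT_SOURCE_MM = (-53.26, 17.3, 19.03)


@dataclass
class SimulationTruth:
    """Ground-truth parameters of one synthetic dataset."""

    source_positions: np.ndarray = dataclass_field(
        default_factory=lambda: np.array([DEFAULT_SOURCE_MM])
    )  # (n_sources, 3) mm
    source_orientations: np.ndarray | None = None  # (n_sources, 3); default: tangential
    amplitude_nam: float = 15.0          # RMS dipole moment, nA·m
    desync_depth: float = 0.4            # fractional amplitude drop during task
    n_trials: int = 120
    task_duration_s: float = 3.0
    rest_duration_s: float = 2.0
    rest_jitter_s: float = 0.0           # uniform jitter of the preceding task offset
    band_hz: tuple[float, float] = (15.0, 30.0)
    ramp_s: float = 0.2                  # cosine envelope ramp
    n_interference: int = 4
    interference_amplitude_t: float = 8e-11   # per-component scale at the channels, tesla
    noise_density_ft: float = 15.0       # white sensor noise, fT/sqrt(Hz)
    sampling_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.source_positions = np.atleast_2d(np.asarray(self.source_positions, float))
        if self.source_orientations is None:
            # tangential orientation maximizes external field for a spherical conductor
            self.source_orientations = np.tile([0.0, 1.0, 0.0], (len(self.source_positions), 1))
        self.source_orientations = np.atleast_2d(np.asarray(self.source_orientations, float))
        norms = np.linalg.norm(self.source_orientations, axis=1)
        self.source_orientations = self.source_orientations / norms[:, None]
        if not 0.0 <= self.desync_depth <= 1.0:
            raise ValidationError(f"desync_depth must be in [0, 1], got {self.desync_depth}")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.sampling_rate < 2.0 * self.band_hz[1]:
            raise ConfigurationError(
                f"sampling rate {self.sampling_rate} Hz cannot represent {self.band_hz[1]} Hz"
            )
        if self.ramp_s > self.task_duration_s:
            raise ConfigurationError("ramp longer than the task period")


def _band_limited_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float,
                        band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to ``band`` (zero-phase), batched on last axis."""
    pad = int(fs)  # 1 s padding absorbs filter edge transients
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    draw = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    x = signal.sosfiltfilt(sos, draw, axis=-1)[..., pad:-pad]
    return x / np.sqrt(np.mean(x**2, axis=-1, keepdims=True))


def _envelope(times: np.ndarray, truth: SimulationTruth, prev_offset: np.ndarray) -> np.ndarray:
    """(n_trials, n_samples) amplitude envelope: 1 at rest, (1 - depth) in task, cosine ramps.

    ``prev_offset`` is the per-trial end time of the previous task period
    (visible before the epoch start unless rest is jittered shorter).
    """
    g = 1.0 - truth.desync_depth
    t = times[None, :]
    po = prev_offset[:, None]

    def ramp(t0, lo, hi):
        x = np.clip((t - t0) / truth.ramp_s, 0.0, 1.0)
        return lo + (hi - lo) * 0.5 * (1.0 - np.cos(np.pi * x))

    env = np.where(t < po, g, ramp(po, g, 1.0))
    env = np.where(t >= 0.0, ramp(0.0, 1.0, g), env)
    if times[-1] >= truth.task_duration_s:
        env = np.where(t >= truth.task_duration_s, ramp(truth.task_duration_s, g, 1.0), env)
    return env


def _interference_mixing(rng: np.random.Generator, n_channels: int,
                         ref_idx: np.ndarray, k: int) -> np.ndarray:
    """(n_channels, k) spatial patterns.

    When k <= n_reference the reference block is redrawn until well
    conditioned, so scalp interference lies exactly in the reference span and
    reference regression is well-specified.  k > n_reference deliberately
    breaks that (misspecified-interference stress case).
    """
    if k > len(ref_idx):
        return rng.standard_normal((n_channels, k))
    for _ in range(50):
        m = rng.standard_normal((n_channels, k))
        if np.linalg.cond(m[ref_idx]) < 1e3:
            return m
    return m


def _interference_basis(rng: np.random.Generator, n_trials: int, n: int, fs: float,
                        k: int) -> np.ndarray:
    """(n_trials, k, n) unit-RMS basis: slow drifts, then 50/77 Hz lines with slow AM."""
    t = np.arange(n) / fs
    sos_lo = signal.butter(4, min(8.0, 0.4 * fs / 2), btype="lowpass", fs=fs, output="sos")
    pad = int(fs)

    def slow(shape):
        x = signal.sosfiltfilt(sos_lo, rng.standard_normal(shape + (n + 2 * pad,)), axis=-1)
        x = x[..., pad:-pad]
        return x / np.sqrt(np.mean(x**2, axis=-1, keepdims=True))

    comps = np.empty((n_trials, k, n))
    line_freqs = [50.0, 77.0]
    n_lines = min(2, max(0, k - 2))
    n_slow = k - n_lines
    comps[:, :n_slow] = slow((n_trials, n_slow))
    if n_lines:
        am = 1.0 + 0.3 * slow((n_trials, n_lines))
        phase = rng.uniform(0, 2 * np.pi, (n_trials, n_lines, 1))
        x = am * np.sin(2 * np.pi * np.asarray(line_freqs[:n_lines])[None, :, None] * t + phase)
        comps[:, n_slow:] = x / np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return comps


def optimal_tangential_orientation(array: SensorArray, sphere, source_pos) -> np.ndarray:
    """Unit moment direction maximizing total sensed field energy at ``source_pos``.

    The radial direction is silent in a spherical conductor, so this is
    always (numerically) tangential; useful as a well-coupled simulation
    default when no physiological orientation is prescribed.
    """
    L = point_leadfield(array, sphere, np.asarray(source_pos, float))
    _, vecs = np.linalg.eigh(L.T @ L)
    return vecs[:, -1]


def simulate_dataset(
    truth: SimulationTruth,
    array: SensorArray,
    leadfields: LeadFieldSet,
    return_components: bool = False,
) -> TrialDataset | tuple[TrialDataset, dict]:
    """Generate a trial-epoched dataset from ground truth.

    ``leadfields`` supplies the conductor sphere; source lead fields are
    evaluated at the exact source positions, not snapped to the grid.  With
    ``return_components=True`` the per-trial brain, interference, and noise
    contributions are returned for oracle-style verification.
    """
    sphere = leadfields.sphere
    d = np.linalg.norm(truth.source_positions - sphere.center, axis=1)
    if np.any(d >= sphere.radius):
        raise ConfigurationError("simulated source lies outside the conductor sphere")

    fs = truth.sampling_rate
    times = np.arange(
        -round(truth.rest_duration_s * fs), round(truth.task_duration_s * fs)
    ) / fs
    n = len(times)
    rng = np.random.default_rng(truth.seed)

    scalp_idx = array.scalp_indices
    ref_idx = array.reference_indices
    n_ch = array.n_channels

    # per-source fixed sensor patterns (tesla per unit source waveform)
    patterns = np.stack(
        [
            point_leadfield(array, sphere, pos) @ (ori * truth.amplitude_nam * 1e-9)
            for pos, ori in zip(truth.source_positions, truth.source_orientations)
        ]
    )  # (n_sources, n_scalp)

    mixing = _interference_mixing(rng, n_ch, ref_idx, truth.n_interference)
    noise_sigma = truth.noise_density_ft * 1e-15 * np.sqrt(fs / 2.0)
    events = np.tile([0.0, truth.task_duration_s], (truth.n_trials, 1))

    if truth.rest_jitter_s:
        jitter = rng.uniform(-truth.rest_jitter_s, truth.rest_jitter_s, truth.n_trials)
    else:
        jitter = np.zeros(truth.n_trials)
    env = _envelope(times, truth, -truth.rest_duration_s + jitter)  # (trials, n)

    n_src = len(truth.source_positions)
    source_wavs = _band_limited_noise(
        rng, (truth.n_trials, n_src, n), fs, truth.band_hz
    ) * env[:, None, :]
    # brain signal at scalp sensors: sum of per-source rank-1 projections
    brain = np.einsum("sc,tsn->tcn", patterns, source_wavs)

    basis = _interference_basis(rng, truth.n_trials, n, fs, truth.n_interference)
    interference = truth.interference_amplitude_t * np.einsum("ck,tkn->tcn", mixing, basis)
    noise = noise_sigma * rng.standard_normal((truth.n_trials, n_ch, n))

    data = interference + noise
    data[:, scalp_idx, :] += brain

    ds = TrialDataset(
        data=data,
        sampling_rate=fs,
        times=times,
        events=events,
        array=array,
        provenance=[{
            "op": "simulate",
            "seed": int(truth.seed),
            "n_trials": int(truth.n_trials),
            "desync_depth": float(truth.desync_depth),
            "amplitude_nam": float(truth.amplitude_nam),
            "source_positions_mm": truth.source_positions.tolist(),
        }],
        seed=truth.seed,
    )
    violations = ds.range_violations()
    if len(violations):
        warnings.warn(
            f"{len(violations)} trial/channel pairs exceed the ±{DYNAMIC_RANGE_T*1e9:.1f} nT "
            f"dynamic range (first: trial {violations[0][0]}, channel {violations[0][1]}); "
            "values are flagged, not clipped",
            stacklevel=2,
        )
        ds.provenance[0]["range_violations"] = violations.tolist()

    if return_components:
        return ds, {
            "source": source_wavs,
            "envelope": env,
            "brain": brain,
            "interference": interference,
            "noise": noise,
            "mixing": mixing,
            "patterns": patterns,
        }
    return ds
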