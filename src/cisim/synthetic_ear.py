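"""Seeded synthetic cohorts of extracochlear electrocochleography recordings.

This module emulates the raw material of an intraoperative guinea-pig
cochlear-implantation experiment: for each ear and surgical condition
(``initial`` recording, after ``cochleostomy``, after electrode
``inserted``) it synthesises averaged round-window recordings on a
frequency x level x polarity stimulus lattice.  Each trace contains

* a compound action potential (CAP): an N1 trough followed by a P1 peak
  whose peak-to-peak amplitude grows linearly with sensation level
  (``cap_gain`` microvolt per dB above the ear's effective threshold) and
  whose latency shortens toward high levels,
* a cochlear microphonic (CM): a copy of the tone burst whose sign follows
  stimulus polarity, so that condensation/rarefaction averaging cancels it,
* additive Gaussian noise representing the residual noise of the
  20-presentation average.

Insertion trauma is injected in the threshold domain as a rising logistic
in log-frequency (high frequencies, near the electrode, are shifted most;
the low-frequency apex is spared).  Ground truth (baseline audiogram,
trauma profile, per-ear seeds) is retained so downstream estimators can be
validated against what was injected.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

CONDITIONS = ("initial", "cochleostomy", "inserted")
#: stimulus polarities: +1 condensation, -1 rarefaction
POLARITIES = (1, -1)
GROUPS = ("5Ch", "6Ch")


# ---------------------------------------------------------------------------
# stimulus lattice
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusGrid:
    """Frequency x level x polarity stimulus lattice and tone-burst timing.

    Frequencies must be logarithmically spaced and strictly increasing,
    levels strictly increasing with a constant step, and the rise/fall
    ramps must fit inside the burst (``2*ramp_duration <= burst_duration``).
    Durations are in seconds, frequencies in Hz, levels in dB SPL.
    """

    frequencies: np.ndarray
    levels: np.ndarray
    burst_duration: float = 0.005
    ramp_duration: float = 0.0025
    sample_rate: float = 100_000.0
    n_averages: int = 20
    pre_stimulus_duration: float = 0.005
    post_onset_duration: float = 0.020

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "levels", levels)
        if freqs.size < 1 or np.any(freqs <= 0):
            raise ValueError("frequencies must be positive and non-empty")
        if freqs.size > 1:
            ratios = np.diff(np.log2(freqs))
            if np.any(ratios <= 0) or not np.allclose(ratios, ratios[0], atol=1e-9):
                raise ValueError("frequencies must be strictly increasing and log-spaced")
        if levels.size < 1:
            raise ValueError("levels must be non-empty")
        if levels.size > 1:
            steps = np.diff(levels)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-9):
                raise ValueError("levels must be strictly increasing with constant step")
        if 2 * self.ramp_duration > self.burst_duration + 1e-12:
            raise ValueError("2*ramp_duration must not exceed burst_duration")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.post_onset_duration < 0.010:
            raise ValueError("analysis epoch must cover >= 10 ms post onset")

    # -- derived quantities -------------------------------------------------

    @property
    def level_step(self) -> float:
        if self.levels.size < 2:
            return 10.0
        return float(self.levels[1] - self.levels[0])

    @property
    def onset_index(self) -> int:
        return int(round(self.pre_stimulus_duration * self.sample_rate))

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_stimulus_duration + self.post_onset_duration) * self.sample_rate))

    def times_post_onset(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.onset_index) / self.sample_rate

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frequencies"] = [float(f) for f in self.frequencies]
        d["levels"] = [float(l) for l in self.levels]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StimulusGrid":
        return cls(**{k: (np.asarray(v, float) if k in ("frequencies", "levels") else v) for k, v in d.items()})


def stimulus_grid(
    f_min: float = 2000.0,
    f_max: float = 32000.0,
    steps_per_octave: int = 4,
    l_min: float = 0.0,
    l_max: float = 90.0,
    l_step: float = 10.0,
    **kwargs,
) -> StimulusGrid:
    """Build the full stimulus lattice.

    The default grid is the study's: 2-32 kHz at 4 steps/octave (17 tone
    frequencies) crossed with 0-90 dB SPL in 10 dB steps (10 levels).
    ``f_max`` must sit an integer number of lattice steps above ``f_min``
    and ``l_step`` must divide ``l_max - l_min``.
    """
    if f_min <= 0 or f_max <= 0:
        raise ValueError("frequencies must be positive")
    if steps_per_octave < 1:
        raise ValueError("steps_per_octave must be >= 1")
    if l_step <= 0:
        raise ValueError("level step must be positive")
    n_fsteps = np.log2(f_max / f_min) * steps_per_octave
    if n_fsteps < 0 or abs(n_fsteps - round(n_fsteps)) > 1e-9:
        raise ValueError("f_max must be an integer number of lattice steps above f_min")
    n_lsteps = (l_max - l_min) / l_step
    if n_lsteps < 0 or abs(n_lsteps - round(n_lsteps)) > 1e-9:
        raise ValueError("l_step must divide l_max - l_min")
    freqs = f_min * 2.0 ** (np.arange(round(n_fsteps) + 1) / steps_per_octave)
    levels = l_min + l_step * np.arange(round(n_lsteps) + 1)
    return StimulusGrid(frequencies=freqs, levels=levels, **kwargs)


def tone_burst(frequency: float, polarity: int, grid: StimulusGrid) -> np.ndarray:
    """Cosine-ramped tone burst at unit amplitude.

    Rarefaction (``polarity=-1``) is the exact negation of condensation.
    The envelope follows raised-cosine rise/fall ramps of
    ``grid.ramp_duration`` and reaches its plateau exactly at the end of
    the rise ramp; with the default 5 ms burst and 2.5 ms ramps the
    plateau has zero length.
    """
    if polarity not in (1, -1):
        raise ValueError("polarity must be +1 (condensation) or -1 (rarefaction)")
    if frequency >= grid.sample_rate / 2:
        raise ValueError("stimulus frequency must lie below Nyquist")
    if frequency <= 0:
        raise ValueError("stimulus frequency must be positive")
    n = int(round(grid.burst_duration * grid.sample_rate))
    t = np.arange(n) / grid.sample_rate
    env = np.ones(n)
    ramp = grid.ramp_duration
    if ramp > 0:
        rising = t < ramp
        env[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / ramp))
        falling = t > grid.burst_duration - ramp
        env[falling] = 0.5 * (1.0 - np.cos(np.pi * (grid.burst_duration - t[falling]) / ramp))
    return polarity * env * np.sin(2 * np.pi * frequency * t)


# ---------------------------------------------------------------------------
# trauma model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraumaProfile:
    """Frequency profile of the insertion-induced threshold shift.

    ``TS(f) = ts_max * logistic(log2(f / f_edge) / slope_w)``: a smooth,
    non-decreasing shift that spares the apex (low frequencies) and
    saturates at ``ts_max`` basally, mimicking trauma concentrated around
    and basal to the electrode tip.  ``f_edge`` is the frequency of the
    half-maximal shift and ``slope_w`` the transition width in octaves.
    """

    ts_max: float
    f_edge: float
    slope_w: float
    cochleostomy_jitter_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.ts_max < 0:
            raise ValueError("ts_max must be >= 0")
        if self.slope_w <= 0:
            raise ValueError("slope_w must be > 0")
        if not (2000.0 <= self.f_edge <= 32000.0):
            raise ValueError("f_edge must lie within the 2-32 kHz grid span")
        if self.cochleostomy_jitter_sd < 0:
            raise ValueError("cochleostomy_jitter_sd must be >= 0")


def trauma_shift(f, profile: TraumaProfile):
    """Injected threshold shift (dB) at frequency ``f`` (Hz, scalar or array)."""
    f = np.asarray(f, dtype=float)
    out = profile.ts_max * expit(np.log2(f / profile.f_edge) / profile.slope_w)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# ground truth per ear
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EarGroundTruth:
    """Everything needed to regenerate and to validate one synthetic ear."""

    ear_id: str
    group: str
    baseline_thresholds: np.ndarray  # dB SPL per grid frequency
    trauma: TraumaProfile
    cap_gain: float = 4.0  # microvolt p2p per dB sensation level
    noise_sd: float = 0.3  # microvolt, post-averaging
    cm_gain: float = 1.0  # microvolt CM amplitude at 60 dB SPL
    seed: int = 0
    tip_depth_um: float | None = None  # carrier-tip arc depth on the spiral
    cochleostomy_jitter: np.ndarray | None = None  # dB per grid frequency

    def __post_init__(self) -> None:
        base = np.asarray(self.baseline_thresholds, dtype=float)
        object.__setattr__(self, "baseline_thresholds", base)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if np.any(base < 0) or np.any(base > 80):
            raise ValueError("baseline thresholds must lie in [0, 80] dB SPL (normal hearing)")
        if self.cochleostomy_jitter is not None:
            jit = np.asarray(self.cochleostomy_jitter, dtype=float)
            if jit.shape != base.shape:
                raise ValueError("cochleostomy_jitter must align with baseline_thresholds")
            object.__setattr__(self, "cochleostomy_jitter", jit)

    def effective_thresholds(self, condition: str, grid: StimulusGrid) -> np.ndarray:
        """Per-frequency threshold (dB SPL) in the given surgical condition."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        if self.baseline_thresholds.shape != grid.frequencies.shape:
            raise ValueError("ground truth does not match grid frequency lattice")
        eff = self.baseline_thresholds.copy()
        if condition == "cochleostomy" and self.cochleostomy_jitter is not None:
            eff = eff + self.cochleostomy_jitter
        elif condition == "inserted":
            eff = eff + trauma_shift(grid.frequencies, self.trauma)
        return eff

    def to_dict(self) -> dict:
        return {
            "ear_id": self.ear_id,
            "group": self.group,
            "baseline_thresholds": [float(x) for x in self.baseline_thresholds],
            "trauma": dataclasses.asdict(self.trauma),
            "cap_gain": self.cap_gain,
            "noise_sd": self.noise_sd,
            "cm_gain": self.cm_gain,
            "seed": int(self.seed),
            "tip_depth_um": self.tip_depth_um,
            "cochleostomy_jitter": None
            if self.cochleostomy_jitter is None
            else [float(x) for x in self.cochleostomy_jitter],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EarGroundTruth":
        d = dict(d)
        d["trauma"] = TraumaProfile(**d["trauma"])
        return cls(**d)


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------


@dataclass
class RecordingSet:
    """Averaged waveforms for one ear and condition.

    ``waveforms`` has shape ``(n_frequencies, n_levels, 2, n_samples)``
    (microvolt); axis 2 holds the two stimulus polarities in the order
    condensation, rarefaction.
    """

    ear_id: str
    condition: str
    waveforms: np.ndarray
    grid: StimulusGrid

    def __post_init__(self) -> None:
        expected = (self.grid.frequencies.size, self.grid.levels.size, 2, self.grid.n_samples)
        if self.waveforms.shape != expected:
            raise ValueError(f"waveforms must have shape {expected}, got {self.waveforms.shape}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def sample_rate(self) -> float:
        return self.grid.sample_rate

    @property
    def pre_stimulus_duration(self) -> float:
        return self.grid.pre_stimulus_duration


def cap_template(grid: StimulusGrid, level: float) -> np.ndarray:
    """CAP waveform template at unit peak-to-peak amplitude.

    Difference of two sharp gamma-like bumps (~0.5 ms wide, so the shape
    survives the 200 Hz - 5 kHz offline band-pass) giving an N1 trough
    near 1.8 ms and a P1 peak near 3.0 ms at the highest stimulus level;
    the whole complex translates 0.5 ms later per 20 dB toward lower
    levels, leaving its shape (and hence its filtered p2p factor) intact.
    """
    shift_s = 0.025e-3 * max(0.0, float(grid.levels[-1]) - level)
    t = grid.times_post_onset() - shift_s
    q = 30.0

    def bump(t_peak: float) -> np.ndarray:
        u = np.clip(t / t_peak, 0.0, None)
        out = np.zeros_like(u)
        pos = u > 0
        out[pos] = np.exp(q * np.log(u[pos]) + q * (1.0 - u[pos]))
        return out

    w = 0.7 * bump(3.0e-3) - bump(1.8e-3)
    return w / np.ptp(w)


def synth_recording_set(
    truth: EarGroundTruth,
    condition: str,
    grid: StimulusGrid,
    seed: int | None = None,
) -> RecordingSet:
    """Synthesise the averaged recording set for one ear and condition.

    Each waveform is ``cap + cm + noise`` where the CAP peak-to-peak
    amplitude is ``cap_gain * max(0, level - effective_threshold)``, the CM
    is the tone burst scaled linearly with sound pressure (``cm_gain`` uV
    at 60 dB SPL) and signed by polarity, and the noise is white Gaussian
    with ``noise_sd`` uV per sample.  Reproducible: the default seed is
    derived from ``truth.seed`` and the condition index.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    eff = truth.effective_thresholds(condition, grid)
    n_f, n_l, n_s = grid.frequencies.size, grid.levels.size, grid.n_samples
    if seed is None:
        rng = default_rng(SeedSequence(entropy=int(truth.seed), spawn_key=(CONDITIONS.index(condition),)))
    else:
        rng = default_rng(seed)

    wav = rng.standard_normal((n_f, n_l, 2, n_s)) * truth.noise_sd

    # CAP: identical in both polarities, so it survives polarity averaging.
    sensation = np.clip(grid.levels[None, :] - eff[:, None], 0.0, None)  # (F, L)
    for j, level in enumerate(grid.levels):
        tpl = cap_template(grid, float(level))  # unit p2p
        wav[:, j, :, :] += (truth.cap_gain * sensation[:, j])[:, None, None] * tpl[None, None, :]

    # CM: follows the stimulus and inverts with polarity.
    onset = grid.onset_index
    n_burst = int(round(grid.burst_duration * grid.sample_rate))
    cm_amp = truth.cm_gain * 10.0 ** ((grid.levels - 60.0) / 20.0)  # (L,)
    for i, f in enumerate(grid.frequencies):
        burst = tone_burst(float(f), 1, grid)
        for k, pol in enumerate(POLARITIES):
            wav[i, :, k, onset : onset + n_burst] += cm_amp[:, None] * (pol * burst)[None, :]

    return RecordingSet(ear_id=truth.ear_id, condition=condition, waveforms=wav, grid=grid)


# ---------------------------------------------------------------------------
# cohort configuration and generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for a synthetic 24-ear cohort.

    Group calibration targets the printed per-group mean of the per-ear
    maximal threshold shift (23.0 dB for deep 6-contact insertions, 10.0 dB
    for shallow 5-contact insertions) with per-ear SD = SEM * sqrt(n_group),
    clipped at zero; the pre-clip mean is solved so the clipped draw keeps
    the target mean.  Electrode depths reproduce the printed group means
    and SDs of the apical-contact (Ch1) insertion depth.
    """

    n_ears: int = 24
    n_shallow: int = 12  # ears in the 5Ch group; the rest are 6Ch
    group_mean_max_ts: Mapping[str, float] = field(
        default_factory=lambda: {"5Ch": 10.0, "6Ch": 23.0}
    )
    group_sem_max_ts: Mapping[str, float] = field(
        default_factory=lambda: {"5Ch": 4.5, "6Ch": 3.5}
    )
    f_edge: Mapping[str, float] = field(
        default_factory=lambda: {"5Ch": 9500.0, "6Ch": 6700.0}
    )
    slope_w: float = 0.35
    cochleostomy_jitter_sd: float = 2.0
    cap_gain: float = 4.0
    noise_sd: float = 0.3
    cm_gain: float = 1.0
    ch1_depth_mean: Mapping[str, float] = field(
        default_factory=lambda: {"5Ch": 4447.75, "6Ch": 5339.56}
    )
    ch1_depth_sd: Mapping[str, float] = field(
        default_factory=lambda: {"5Ch": 290.23, "6Ch": 306.45}
    )
    tip_to_ch1_um: float = 1000.0
    baseline_offset_range: tuple[float, float] = (18.0, 30.0)
    grid: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_ears < 1:
            raise ValueError("n_ears must be >= 1")
        if not (0 <= self.n_shallow <= self.n_ears):
            raise ValueError("n_shallow must lie in [0, n_ears]")

    def make_grid(self) -> StimulusGrid:
        return stimulus_grid(**dict(self.grid))

    def group_sizes(self) -> dict[str, int]:
        return {"5Ch": self.n_shallow, "6Ch": self.n_ears - self.n_shallow}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in d.items()}
        d["baseline_offset_range"] = list(self.baseline_offset_range)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        if "baseline_offset_range" in d:
            d["baseline_offset_range"] = tuple(d["baseline_offset_range"])
        return cls(**d)


def _preclip_mean(target_mean: float, sd: float) -> float:
    """Pre-clip mean mu such that E[max(0, N(mu, sd^2))] == target_mean."""
    if sd == 0 or target_mean <= 0:
        return target_mean

    def excess(mu: float) -> float:
        z = mu / sd
        return mu * norm.cdf(z) + sd * norm.pdf(z) - target_mean

    return float(brentq(excess, target_mean - 12 * sd - 1.0, target_mean + 1.0, xtol=1e-10))


def _baseline_audiogram(
    freqs: np.ndarray, rng, offset_range: tuple[float, float] = (18.0, 30.0)
) -> tuple[float, np.ndarray]:
    """Smooth normal-hearing CAP audiogram: flat above 4 kHz, mildly raised
    toward the 2 kHz edge, with a small smooth ear-specific undulation."""
    offset = rng.uniform(*offset_range)
    low_boost = 6.0 * np.clip(np.log2(4000.0 / freqs), 0.0, None)
    phase = rng.uniform(0.0, 2 * np.pi)
    octaves = np.log2(freqs / freqs[0])
    wiggle = 0.75 * np.sin(2 * np.pi * 1.1 * octaves / max(octaves[-1], 1.0) + phase)
    return offset, np.clip(offset + low_boost + wiggle, 0.0, 80.0)


def cohort_truths(config: CohortConfig | None = None, master_seed: int = 0) -> list[EarGroundTruth]:
    """Draw the ground truth for every ear of a cohort.

    Per-ear seeds are derived deterministically from ``master_seed`` and the
    ear index (``SeedSequence(master_seed, spawn_key=(index,))``), so single
    ears can be regenerated without rebuilding the cohort.
    """
    config = config or CohortConfig()
    grid = config.make_grid()
    freqs = grid.frequencies
    sizes = config.group_sizes()
    preclip = {
        g: _preclip_mean(
            float(config.group_mean_max_ts[g]),
            float(config.group_sem_max_ts[g]) * np.sqrt(max(sizes[g], 1)),
        )
        for g in GROUPS
    }
    plateau = {
        g: float(expit(np.log2(freqs[-1] / config.f_edge[g]) / config.slope_w)) for g in GROUPS
    }

    truths: list[EarGroundTruth] = []
    for i in range(config.n_ears):
        group = "5Ch" if i < config.n_shallow else "6Ch"
        ss = SeedSequence(entropy=int(master_seed), spawn_key=(i,))
        rng = default_rng(ss)
        ear_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
        _, base = _baseline_audiogram(freqs, rng, config.baseline_offset_range)
        sd = float(config.group_sem_max_ts[group]) * np.sqrt(max(sizes[group], 1))
        max_ts = max(0.0, rng.normal(preclip[group], sd))
        # ts_max is scaled so the injected maximum over the lattice equals max_ts
        ts_max = max_ts / plateau[group]
        trauma = TraumaProfile(
            ts_max=ts_max,
            f_edge=float(config.f_edge[group]),
            slope_w=config.slope_w,
            cochleostomy_jitter_sd=config.cochleostomy_jitter_sd,
        )
        jitter = rng.normal(0.0, config.cochleostomy_jitter_sd, size=freqs.size)
        ch1_depth = rng.normal(
            float(config.ch1_depth_mean[group]), float(config.ch1_depth_sd[group])
        )
        truths.append(
            EarGroundTruth(
                ear_id=f"ear{i:02d}",
                group=group,
                baseline_thresholds=base,
                trauma=trauma,
                cap_gain=config.cap_gain,
                noise_sd=config.noise_sd,
                cm_gain=config.cm_gain,
                seed=ear_seed,
                tip_depth_um=float(ch1_depth + config.tip_to_ch1_um),
                cochleostomy_jitter=jitter,
            )
        )
    return truths


def synth_cohort(
    config: CohortConfig | None = None, master_seed: int = 0
) -> list[tuple[EarGroundTruth, dict[str, RecordingSet]]]:
    """Generate a full cohort eagerly: (ground truth, recordings per condition).

    Note: with the default full-size grid this materialises ~0.5 GB of
    waveforms; prefer :func:`cohort_truths` plus per-ear
    :func:`synth_recording_set` for streaming analysis of large cohorts.
    """
    config = config or CohortConfig()
    grid = config.make_grid()
    out = []
    for truth in cohort_truths(config, master_seed):
        recs = {cond: synth_recording_set(truth, cond, grid) for cond in CONDITIONS}
        out.append((truth, recs))
    return out


# ---------------------------------------------------------------------------
# bundle I/O (per-ear directory with meta.json + waveforms)
# ---------------------------------------------------------------------------


def write_bundle(
    ear_dir: str | Path,
    recordings: Mapping[str, RecordingSet],
    truth: EarGroundTruth | None = None,
    config_hash: str = "",
    fmt: str = "csv",
) -> Path:
    """Write one ear's recordings as a bundle directory.

    ``csv`` writes a long-format ``waveforms.csv`` (condition, frequency_hz,
    level_db, polarity, sample_index, microvolts; samples rounded to
    1e-6 uV); ``npz`` writes an equivalent binary ``waveforms.npz``.
    ``meta.json`` round-trips the grid and sampling metadata exactly.
    """
    ear_dir = Path(ear_dir)
    ear_dir.mkdir(parents=True, exist_ok=True)
    first = next(iter(recordings.values()))
    meta = {
        "ear_id": first.ear_id,
        "grid": first.grid.to_dict(),
        "conditions": sorted(recordings.keys(), key=CONDITIONS.index),
        "sample_rate": first.grid.sample_rate,
        "pre_stimulus_duration": first.grid.pre_stimulus_duration,
        "format": fmt,
        "config_hash": config_hash,
    }
    if truth is not None:
        meta["group"] = truth.group
    (ear_dir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    if fmt == "npz":
        arrays = {cond: rs.waveforms for cond, rs in recordings.items()}
        np.savez_compressed(ear_dir / "waveforms.npz", **arrays)
        return ear_dir
    if fmt != "csv":
        raise ValueError("fmt must be 'csv' or 'npz'")

    frames = []
    for cond in meta["conditions"]:
        rs = recordings[cond]
        n_f, n_l, _, n_s = rs.waveforms.shape
        idx = pd.MultiIndex.from_product(
            [rs.grid.frequencies, rs.grid.levels, list(POLARITIES), np.arange(n_s)],
            names=["frequency_hz", "level_db", "polarity", "sample_index"],
        )
        df = pd.DataFrame({"microvolts": rs.waveforms.reshape(-1)}, index=idx).reset_index()
        df.insert(0, "condition", cond)
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    long.to_csv(ear_dir / "waveforms.csv", index=False, float_format="%.6f")
    return ear_dir


def read_bundle(ear_dir: str | Path) -> dict[str, RecordingSet]:
    """Read a bundle directory written by :func:`write_bundle`."""
    ear_dir = Path(ear_dir)
    meta = json.loads((ear_dir / "meta.json").read_text())
    grid = StimulusGrid.from_dict(meta["grid"])
    shape = (grid.frequencies.size, grid.levels.size, 2, grid.n_samples)
    out: dict[str, RecordingSet] = {}
    if meta.get("format", "csv") == "npz":
        with np.load(ear_dir / "waveforms.npz") as npz:
            for cond in meta["conditions"]:
                out[cond] = RecordingSet(meta["ear_id"], cond, npz[cond].reshape(shape), grid)
        return out
    long = pd.read_csv(ear_dir / "waveforms.csv")
    for cond in meta["conditions"]:
        sub = long[long["condition"] == cond].sort_values(
            ["frequency_hz", "level_db", "polarity", "sample_index"],
            ascending=[True, True, False, True],  # +1 (condensation) first
            kind="mergesort",
        )
        wav = sub["microvolts"].to_numpy().reshape(shape)
        out[cond] = RecordingSet(meta["ear_id"], cond, wav, grid)
    return out
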