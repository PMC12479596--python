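"""Synthetic resting-state EEG cohorts with planted microstate structure.

The generator emulates eyes-closed pediatric resting EEG as the downstream
pipeline sees it: a small set of quasi-stable, dipolar scalp topographies
that dominate the signal for ~60-120 ms at a time, an alpha-band (10 Hz)
amplitude envelope that produces GFP peaks at a realistic rate, spatially
correlated sensor noise, and two groups whose microstate dynamics differ by
configurable effects (by default a longer map-C dwell in group B).

Every random draw flows from an integer seed through ``numpy.random``
SeedSequence spawning, so all outputs reproduce bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GenerationError, InvalidArgumentError
from .io import Recording

__all__ = [
    "SimulationTruth",
    "StateSequence",
    "GroupEffects",
    "make_montage",
    "make_template_maps",
    "default_truth",
    "simulate_state_sequence",
    "sequence_metrics",
    "simulate_recording",
    "simulate_cohort",
]

#: carrier frequency of the amplitude envelope (Hz); eyes-closed alpha
ALPHA_HZ = 10.0
#: additive floor keeping the envelope strictly positive
ENVELOPE_FLOOR = 0.1
#: probability that the active template's polarity flips at a GFP trough.
#: Mostly-alternating signs (as in a genuine 10 Hz oscillation) keep the
#: spectrum alpha-peaked while still exercising polarity invariance.
FLIP_PROB = 0.8


@dataclass
class SimulationTruth:
    """Ground-truth generative parameters for one cohort.

    ``template_maps`` rows are unit-norm, average-referenced topographies;
    ``transition_matrix`` is row-stochastic with a structurally zero
    diagonal (no self-transitions at the run level); ``snr`` is the ratio of
    state-signal RMS to noise RMS.
    """

    template_maps: np.ndarray
    dwell_mean_ms: np.ndarray
    transition_matrix: np.ndarray
    snr: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.template_maps = np.asarray(self.template_maps, dtype=float)
        self.dwell_mean_ms = np.broadcast_to(
            np.asarray(self.dwell_mean_ms, dtype=float), (self.n_maps,)
        ).copy()
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = self.n_maps
        if self.transition_matrix.shape != (k, k):
            raise InvalidArgumentError("transition_matrix must be k x k")
        if np.any(np.diag(self.transition_matrix) != 0):
            raise InvalidArgumentError("transition_matrix diagonal must be exactly 0")
        if k > 1 and not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidArgumentError("transition_matrix rows must sum to 1")
        if np.any(self.dwell_mean_ms <= 0):
            raise InvalidArgumentError("dwell_mean_ms must be positive")
        if not self.snr > 0:
            raise InvalidArgumentError("snr must be positive")
        row_means = self.template_maps.mean(axis=1)
        row_norms = np.linalg.norm(self.template_maps, axis=1)
        if np.any(np.abs(row_means) > 1e-9) or np.any(np.abs(row_norms - 1) > 1e-9):
            raise InvalidArgumentError("template rows must be average-referenced and unit-norm")

    @property
    def n_maps(self) -> int:
        return self.template_maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.template_maps.shape[1]


@dataclass
class StateSequence:
    """Per-sample microstate index (0-based) at sampling rate ``sfreq``."""

    labels: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


@dataclass
class GroupEffects:
    """Multiplicative group-B modifiers of the generative parameters.

    ``dwell`` maps a 0-based map index to a dwell-mean multiplier (default:
    map C, index 2, lengthened by 1.3).  ``transition`` maps an (i, j) pair
    to a multiplier on that transition probability (row renormalized).
    """

    dwell: dict[int, float] = field(default_factory=lambda: {2: 1.3})
    transition: dict[tuple[int, int], float] = field(default_factory=dict)

    def apply(self, truth: SimulationTruth) -> SimulationTruth:
        dwell = truth.dwell_mean_ms.copy()
        for m, factor in self.dwell.items():
            dwell[m] *= factor
        trans = truth.transition_matrix.copy()
        for (i, j), factor in self.transition.items():
            trans[i, j] *= factor
        if truth.n_maps > 1:
            trans /= trans.sum(axis=1, keepdims=True)
        return SimulationTruth(
            template_maps=truth.template_maps,
            dwell_mean_ms=dwell,
            transition_matrix=trans,
            snr=truth.snr,
            seed=truth.seed,
        )


def make_montage(n_channels: int) -> np.ndarray:
    """Deterministic electrode cap: ``n_channels`` distinct points on the
    upper hemisphere of a unit sphere (Fibonacci lattice)."""
    if n_channels < 8:
        raise InvalidArgumentError("need at least 8 channels")
    golden = (1 + 5**0.5) / 2
    i = np.arange(n_channels)
    # z descends from vertex toward (but not onto) the equator
    z = 1.0 - i / n_channels
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    theta = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_template_maps(
    n_maps: int,
    montage: np.ndarray,
    seed: int | np.random.SeedSequence = 0,
    max_abs_corr: float = 0.8,
    max_tries: int = 200,
) -> np.ndarray:
    """Smooth dipolar template topographies with bounded pairwise overlap.

    Each map is the field of a randomly placed and oriented point dipole
    inside the head sphere, average-referenced and scaled to unit norm.
    Candidates too collinear with an accepted map (|r| >= ``max_abs_corr``)
    are rejected so that the group-level merge rule is not triggered by
    construction.
    """
    if not 2 <= n_maps <= 7:
        raise InvalidArgumentError("n_maps must be in [2, 7]")
    montage = np.asarray(montage, dtype=float)
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < n_maps:
        if tries >= max_tries * n_maps:
            raise GenerationError(
                f"could not draw {n_maps} maps with pairwise |r| < {max_abs_corr}"
            )
        tries += 1
        center = 0.5 * rng.normal(size=3)
        center = center / max(1.0, np.linalg.norm(center) / 0.6)
        moment = rng.normal(size=3)
        moment /= np.linalg.norm(moment)
        delta = montage - center
        dist = np.linalg.norm(delta, axis=1)
        v = delta @ moment / dist**3
        v = v - v.mean()
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            continue
        v = v / norm
        if any(abs(float(v @ m)) >= max_abs_corr for m in maps):
            continue
        maps.append(v)
    return np.asarray(maps)


def default_truth(
    n_channels: int = 64,
    n_maps: int = 4,
    dwell_mean_ms=(70.0, 80.0, 90.0, 80.0),
    snr: float = 4.0,
    seed: int = 0,
) -> SimulationTruth:
    """Study-condition defaults: 4 dipolar maps on a 64-channel cap,
    per-map dwell means inside the canonical 60-120 ms range, uniform
    off-diagonal transitions, state-signal SNR 4."""
    montage = make_montage(n_channels)
    maps = make_template_maps(n_maps, montage, seed=seed)
    dwell = np.asarray(dwell_mean_ms, dtype=float)[:n_maps]
    trans = np.full((n_maps, n_maps), 1.0 / max(1, n_maps - 1))
    np.fill_diagonal(trans, 0.0)
    return SimulationTruth(maps, dwell, trans, snr=snr, seed=seed)


def simulate_state_sequence(
    truth: SimulationTruth,
    duration_s: float,
    sfreq: float = 250.0,
    seed: int | np.random.SeedSequence = 0,
) -> StateSequence:
    """Semi-Markov state sequence: per-state geometric dwell (in samples,
    mean ``dwell_mean_ms``), successor drawn from the transition row."""
    if not duration_s > 0:
        raise InvalidArgumentError("duration_s must be positive")
    n_samples = int(round(duration_s * sfreq))
    rng = np.random.default_rng(seed)
    k = truth.n_maps
    mean_samples = truth.dwell_mean_ms * sfreq / 1000.0
    p_leave = np.clip(1.0 / mean_samples, 1e-12, 1.0)
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(k))
    t = 0
    while t < n_samples:
        dwell = int(rng.geometric(p_leave[state]))
        end = min(t + dwell, n_samples)
        labels[t:end] = state
        t = end
        if k > 1:
            state = int(rng.choice(k, p=truth.transition_matrix[state]))
    return StateSequence(labels=labels, sfreq=sfreq)


def _run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (run labels, run lengths)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts


def sequence_metrics(sequence: StateSequence, n_maps: int | None = None) -> pd.DataFrame:
    """Closed-form per-map dynamics of a label sequence: mean dwell (ms),
    coverage (%), occurrence (runs/s).  Satisfies
    coverage = occurrence * mean_duration / 10 exactly."""
    labels = sequence.labels
    if n_maps is None:
        n_maps = int(labels.max()) + 1
    run_labels, run_lens = _run_lengths(labels)
    total_s = labels.size / sequence.sfreq
    rows = []
    for m in range(n_maps):
        lens = run_lens[run_labels == m]
        n_runs = lens.size
        mean_dur = lens.mean() / sequence.sfreq * 1000.0 if n_runs else np.nan
        rows.append(
            {
                "map": m,
                "mean_duration_ms": mean_dur,
                "coverage_pct": lens.sum() / labels.size * 100.0,
                "occurrence_per_s": n_runs / total_s,
                "n_runs": n_runs,
            }
        )
    return pd.DataFrame(rows)


def _spatial_noise(
    montage: np.ndarray, n_samples: int, rng: np.random.Generator, smooth_scale: float = 0.5
) -> np.ndarray:
    """Spatially correlated noise: white channel noise smoothed across
    neighboring electrodes plus 30% white sensor noise."""
    n_ch = montage.shape[0]
    d2 = ((montage[:, None, :] - montage[None, :, :]) ** 2).sum(-1)
    weights = np.exp(-d2 / (2 * smooth_scale**2))
    weights /= np.linalg.norm(weights, axis=1, keepdims=True)
    smooth = weights @ rng.standard_normal((n_ch, n_samples))
    white = rng.standard_normal((n_ch, n_samples))
    return 0.7 * smooth + 0.3 * white


def simulate_recording(
    truth: SimulationTruth,
    sequence: StateSequence,
    montage: np.ndarray,
    snr: float | None = None,
    seed: int | np.random.SeedSequence = 0,
    amplitude_uv: float = 15.0,
) -> Recording:
    """Render a state sequence as multichannel EEG.

    At each sample the noiseless part is the active template times a
    strictly positive alpha-modulated envelope (|sin 2*pi*10t| + floor) and
    a polarity sign that flips at envelope troughs with probability
    ``FLIP_PROB``.  Spatially correlated noise is scaled so that the
    state-signal-to-noise RMS ratio equals ``snr`` exactly.
    """
    montage = np.asarray(montage, dtype=float)
    if montage.shape[0] != truth.n_channels:
        raise InvalidArgumentError("montage channel count does not match truth templates")
    if snr is None:
        snr = truth.snr
    rng = np.random.default_rng(seed)
    labels = sequence.labels
    n = labels.size
    t = np.arange(n) / sequence.sfreq
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * ALPHA_HZ * t + phase)
    envelope = np.abs(carrier) + ENVELOPE_FLOOR

    # polarity: piecewise-constant between envelope troughs (carrier zeros)
    half_period = sequence.sfreq / (2 * ALPHA_HZ)
    pulse_index = np.floor((t * sequence.sfreq + phase * half_period / np.pi) / half_period)
    pulse_index = pulse_index.astype(int) - int(pulse_index[0])
    n_pulses = int(pulse_index[-1]) + 1
    flips = rng.random(n_pulses) < FLIP_PROB
    signs_per_pulse = np.where(np.cumsum(flips) % 2 == 0, 1.0, -1.0)
    sign = signs_per_pulse[pulse_index]

    clean = truth.template_maps[labels].T * (amplitude_uv * envelope * sign)
    if np.isfinite(snr):
        noise = _spatial_noise(montage, n, rng)
        signal_rms = np.sqrt(np.mean(clean**2))
        noise_rms = np.sqrt(np.mean(noise**2))
        noise *= signal_rms / (snr * noise_rms)
        data = clean + noise
    else:
        data = clean
    return Recording(data=data, sfreq=sequence.sfreq)


def simulate_cohort(
    n_per_group: int = 18,
    truth: SimulationTruth | None = None,
    group_effects: GroupEffects | None = None,
    seed: int = 0,
    duration_s: float = 240.0,
    sfreq: float = 250.0,
    n_channels: int = 64,
    subject_dwell_sd: float = 0.1,
) -> tuple[list[Recording], pd.DataFrame]:
    """Two matched groups of synthetic subjects sharing one template set.

    Group "A" uses the base generative parameters; group "B" has
    ``group_effects`` applied (default: map-C dwell mean x 1.3, the planted
    analogue of the headline group difference).  Per-subject dwell means are
    jittered lognormally (sd ``subject_dwell_sd`` on the log scale) to mimic
    between-subject variability.

    Returns the recordings (tagged with subject_id and group) and a tidy
    frame of realized per-subject, per-map sequence metrics (ground truth
    for recovery checks).
    """
    if n_per_group < 2:
        raise InvalidArgumentError("n_per_group must be >= 2")
    if truth is None:
        truth = default_truth(n_channels=n_channels, seed=seed)
    if group_effects is None:
        group_effects = GroupEffects()
    montage = make_montage(truth.n_channels)
    truth_b = group_effects.apply(truth)
    root = np.random.SeedSequence(seed)
    recordings: list[Recording] = []
    metric_rows: list[pd.DataFrame] = []
    for g, g_truth in (("A", truth), ("B", truth_b)):
        for i in range(n_per_group):
            sub_seq_seed, jitter_seed, rec_seed = root.spawn(3)
            root = root.spawn(1)[0]
            jitter_rng = np.random.default_rng(jitter_seed)
            dwell = g_truth.dwell_mean_ms * np.exp(
                jitter_rng.normal(0, subject_dwell_sd, g_truth.n_maps)
            )
            sub_truth = SimulationTruth(
                g_truth.template_maps, dwell, g_truth.transition_matrix,
                snr=g_truth.snr, seed=truth.seed,
            )
            seq = simulate_state_sequence(sub_truth, duration_s, sfreq, seed=sub_seq_seed)
            rec = simulate_recording(sub_truth, seq, montage, seed=rec_seed)
            sid = f"{g}{i:02d}"
            rec = rec.copy_with(subject_id=sid, group=g)
            recordings.append(rec)
            sm = sequence_metrics(seq, n_maps=truth.n_maps)
            sm.insert(0, "subject_id", sid)
            sm.insert(1, "group", g)
            metric_rows.append(sm)
    return recordings, pd.concat(metric_rows, ignore_index=True)
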