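"""Markov-chain transition structure of the microstate label sequence.

Transitions are run-level events: one count per pair of consecutive
distinct-label runs.  Observed row-conditional probabilities are divided by
the probabilities expected if successors were drawn independently in
proportion to map run frequencies (self-transitions excluded from the
normalizing pool, since the diagonal is structurally zero), so normalized
ratios away from 1 indicate genuine sequential structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backfit import UNASSIGNED, Segmentation
from .exceptions import InvalidArgumentError
from .synth import _run_lengths

__all__ = ["TransitionTable", "transition_counts", "run_frequencies", "normalized_transitions"]


@dataclass
class TransitionTable:
    """Off-diagonal transition counts with observed, expected and
    observed/expected probabilities (NaN marks undefined cells)."""

    counts: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    normalized: np.ndarray

    @property
    def n_maps(self) -> int:
        return self.counts.shape[0]

    def to_frame(self, map_labels: list[str] | None = None) -> pd.DataFrame:
        k = self.n_maps
        if map_labels is None:
            map_labels = [chr(ord("A") + i) for i in range(k)]
        rows = []
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append(
                    {
                        "from_map": map_labels[i],
                        "to_map": map_labels[j],
                        "count": int(self.counts[i, j]),
                        "observed": self.observed[i, j],
                        "expected": self.expected[i, j],
                        "normalized": self.normalized[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _assigned_run_labels(segmentation: Segmentation) -> tuple[np.ndarray, np.ndarray]:
    run_labels, _ = _run_lengths(segmentation.labels)
    return run_labels, run_labels[run_labels != UNASSIGNED]


def transition_counts(segmentation: Segmentation) -> np.ndarray:
    """k x k counts of consecutive distinct-label run pairs.

    Transitions into or out of UNASSIGNED stretches are dropped (a run pair
    is counted only when the two runs are adjacent in time and both
    assigned), so the diagonal is structurally zero.
    """
    k = segmentation.n_maps
    run_labels, _ = _run_lengths(segmentation.labels)
    counts = np.zeros((k, k), dtype=int)
    if run_labels.size < 2:
        warnings.warn("fewer than 2 runs: empty transition table")
        return counts
    src, dst = run_labels[:-1], run_labels[1:]
    ok = (src != UNASSIGNED) & (dst != UNASSIGNED)
    np.add.at(counts, (src[ok], dst[ok]), 1)
    return counts


def run_frequencies(segmentation: Segmentation) -> np.ndarray:
    """Number of assigned runs per map."""
    run_labels, _ = _run_lengths(segmentation.labels)
    assigned = run_labels[run_labels != UNASSIGNED]
    return np.bincount(assigned, minlength=segmentation.n_maps)


def normalized_transitions(counts: np.ndarray, run_freq: np.ndarray) -> TransitionTable:
    """Observed / expected transition probabilities.

    observed[i, j] = counts[i, j] / sum_j counts[i, j];
    expected[i, j] = freq_j / sum_{m != i} freq_m (independence given that
    self-transitions are impossible); normalized = observed / expected.
    Rows without counts and cells with zero expected probability are NaN.
    """
    counts = np.asarray(counts, dtype=float)
    run_freq = np.asarray(run_freq, dtype=float)
    k = counts.shape[0]
    if counts.shape != (k, k):
        raise InvalidArgumentError("counts must be square")
    if run_freq.shape != (k,):
        raise InvalidArgumentError("run_freq must have one entry per map")
    if np.any(np.diag(counts) != 0):
        raise InvalidArgumentError("counts diagonal must be zero (no self-transitions)")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(row_sums > 0, counts / row_sums, np.nan)
        pool = run_freq.sum() - run_freq[:, None]  # excludes the source map
        expected = np.where(pool > 0, run_freq[None, :] / pool, np.nan)
        normalized = np.where(expected > 0, observed / expected, np.nan)
    np.fill_diagonal(observed, np.nan)
    np.fill_diagonal(expected, np.nan)
    np.fill_diagonal(normalized, np.nan)
    return TransitionTable(
        counts=counts.astype(int), observed=observed, expected=expected, normalized=normalized
    )
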