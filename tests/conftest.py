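"""Shared fixtures: small deterministic maps and (session-scoped) the
expensive synthetic cohorts reused across recovery and power tests."""

from __future__ import annotations

import numpy as np
import pytest

import mstates as ms
from mstates import (
    GroupEffects,
    TemplateMaps,
    mann_whitney,
    match_templates,
    modified_kmeans,
    normalized_transitions,
    run_frequencies,
    transition_counts,
)


@pytest.fixture(scope="session")
def montage64() -> np.ndarray:
    return ms.make_montage(64)


@pytest.fixture(scope="session")
def truth4(montage64) -> ms.SimulationTruth:
    return ms.default_truth(n_channels=64, seed=1)


@pytest.fixture()
def ortho_templates() -> TemplateMaps:
    """Two orthogonal average-referenced unit-norm 8-channel maps."""
    t = np.zeros((2, 8))
    t[0, 0], t[0, 1] = 1.0, -1.0
    t[1, 2], t[1, 3] = 1.0, -1.0
    t -= t.mean(axis=1, keepdims=True)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return TemplateMaps(t)


@pytest.fixture(scope="session")
def cohort_snr4(truth4):
    """36 preprocessed subjects (18/group, 64 channels, 60 s, snr 4) with
    the default planted map-C dwell effect."""
    recs, truth_metrics = ms.simulate_cohort(
        18, truth=truth4, seed=11, duration_s=60.0
    )
    return [ms.preprocess(r) for r in recs], truth_metrics, truth4


def _effect_replicate(seed: int, effects: GroupEffects):
    """One seeded cohort replicate -> (one-sided map-C dwell p-value,
    direction of the group-mean normalized B->C ratio, worst template
    recovery |r|)."""
    truth = ms.default_truth(seed=seed)
    recs, _ = ms.simulate_cohort(
        18, truth=truth, group_effects=effects, seed=seed, duration_s=60.0
    )
    recs = [ms.preprocess(r) for r in recs]
    pool = []
    for r in recs:
        series = ms.gfp(r)
        peaks = ms.gfp_peaks(series)
        data = r.data - r.data.mean(axis=0)
        pool.append(data[:, peaks[::12]].T)
    _, templates = modified_kmeans(np.vstack(pool), 4, restarts=10, seed=seed)
    order, matched_r = match_templates(templates.maps, truth.template_maps)
    templates = TemplateMaps(templates.maps[order])
    dur_c: dict[str, list[float]] = {"A": [], "B": []}
    norm_bc: dict[str, list[float]] = {"A": [], "B": []}
    for rec in recs:
        seg, metrics = ms.backfit(rec, templates)
        dur_c[rec.group].append(metrics.loc[2, "mean_duration_ms"])
        table = normalized_transitions(transition_counts(seg), run_frequencies(seg))
        norm_bc[rec.group].append(table.normalized[1, 2])
    p = mann_whitney(dur_c["B"], dur_c["A"], alternative="greater").p
    bc_greater = float(np.nanmean(norm_bc["B"])) > float(np.nanmean(norm_bc["A"]))
    return p, bc_greater, float(matched_r.min())


@pytest.fixture(scope="session")
def planted_effect_replicates():
    """20 seeded cohort replicates with a 1.3x map-C dwell effect and a
    1.5x B->C transition bias in group B."""
    effects = GroupEffects(dwell={2: 1.3}, transition={(1, 2): 1.5})
    return [_effect_replicate(1000 + s, effects) for s in range(20)]
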