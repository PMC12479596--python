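"""End-to-end orchestration with file-based stage handoff.

``run_pipeline`` executes simulate/load -> preprocess -> cluster -> backfit
-> transitions -> stats -> spectrum into a results directory of tidy CSV
and JSON files.  Every stage can also be run on its own against the same
working directory (that is what the CLI subcommands do).  Outputs carry the
config hash and seed, and re-running with the same config is bitwise
identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .backfit import Segmentation, backfit as run_backfit
from . import cluster as cl
from . import preproc as pp
from . import spectral as sp
from . import stats as st
from . import synth
from . import transitions as tr
from .config import PipelineConfig, config_hash, validate_config
from .exceptions import InvalidArgumentError
from .io import Recording, read_matrix, write_matrix

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_preprocess",
    "stage_cluster",
    "stage_backfit",
    "stage_transitions",
    "stage_stats",
    "stage_spectrum",
]

log = logging.getLogger("mstates")

PARAM_COLS = ["gev_pct", "mean_duration_ms", "coverage_pct", "occurrence_per_s"]


def _load_recordings(directory: Path) -> list[Recording]:
    recs = [read_matrix(p) for p in sorted(directory.glob("*.tsv"))]
    if not recs:
        raise InvalidArgumentError(f"no recordings (*.tsv) found in {directory}")
    return recs


def _write_recordings(recs: list[Recording], directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for rec in recs:
        write_matrix(rec, directory / f"{rec.subject_id}.tsv")


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config_hash(config), "seed": config.seed}


def _timed(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - self.t0)

    return _Timer()


def stage_simulate(config: PipelineConfig, workdir: Path) -> None:
    sim = config.simulation
    if sim is None:
        raise InvalidArgumentError("config has no simulation block")
    with _timed("simulate"):
        truth = synth.default_truth(
            n_channels=sim.n_channels, n_maps=sim.n_maps, snr=sim.snr, seed=config.seed
        )
        effects = synth.GroupEffects(
            dwell={sim.dwell_effect_map: sim.dwell_effect},
            transition=(
                {sim.transition_effect_pair: sim.transition_effect}
                if sim.transition_effect != 1.0
                else {}
            ),
        )
        recs, truth_metrics = synth.simulate_cohort(
            n_per_group=sim.n_per_group,
            truth=truth,
            group_effects=effects,
            seed=config.seed,
            duration_s=sim.duration_s,
            sfreq=sim.sfreq,
        )
        _write_recordings(recs, workdir / "recordings")
        truth_metrics.to_csv(workdir / "truth_metrics.csv", index=False)
        np.savetxt(workdir / "truth_templates.csv", truth.template_maps, delimiter=",", fmt="%.10g")


def stage_preprocess(config: PipelineConfig, workdir: Path) -> None:
    src = Path(config.input_dir) if config.input_dir else workdir / "recordings"
    with _timed("preprocess"):
        recs = _load_recordings(src)
        p = config.preproc
        out = [
            pp.preprocess(r, low_hz=p.low_hz, high_hz=p.high_hz, notch_hz=p.notch_hz,
                          target_hz=p.target_hz)
            for r in recs
        ]
        _write_recordings(out, workdir / "preprocessed")


def stage_cluster(config: PipelineConfig, workdir: Path) -> None:
    with _timed("cluster"):
        recs = _load_recordings(workdir / "preprocessed")
        c = config.cluster
        templates, audit = cl.two_level_clustering(
            recs,
            k_range=range(c.k_min, c.k_max + 1),
            merge_threshold=c.merge_threshold,
            restarts=c.restarts,
            subject_restarts=c.subject_restarts,
            subject_k=c.subject_k,
            seed=config.seed,
        )
        df = pd.DataFrame(templates.maps, index=templates.labels)
        df.to_csv(workdir / "templates.csv", header=False)
        audit.update(_provenance(config))
        (workdir / "cluster_audit.json").write_text(json.dumps(audit, indent=1, default=str))


def _read_templates(workdir: Path) -> cl.TemplateMaps:
    raw = pd.read_csv(workdir / "templates.csv", header=None, index_col=0)
    return cl.TemplateMaps(maps=raw.to_numpy(float), labels=[str(i) for i in raw.index])


def stage_backfit(config: PipelineConfig, workdir: Path) -> None:
    with _timed("backfit"):
        recs = _load_recordings(workdir / "preprocessed")
        templates = _read_templates(workdir)
        b = config.backfit
        seg_dir = workdir / "segmentations"
        seg_dir.mkdir(exist_ok=True)
        frames = []
        for rec in recs:
            seg, metrics = run_backfit(
                rec, templates, threshold=b.threshold, half_window=b.half_window,
                strength=b.strength,
            )
            seg.to_frame().to_csv(seg_dir / f"{rec.subject_id}.csv", index=False)
            metrics.insert(0, "subject_id", rec.subject_id)
            metrics.insert(1, "group", rec.group)
            frames.append(metrics)
        all_metrics = pd.concat(frames, ignore_index=True)
        all_metrics["map"] = all_metrics["map"].map(lambda m: templates.labels[m])
        all_metrics.to_csv(workdir / "metrics.csv", index=False)


def stage_transitions(config: PipelineConfig, workdir: Path) -> None:
    with _timed("transitions"):
        recs = _load_recordings(workdir / "preprocessed")
        templates = _read_templates(workdir)
        k = templates.n_maps
        frames = []
        for rec in recs:
            seg_df = pd.read_csv(workdir / "segmentations" / f"{rec.subject_id}.csv")
            seg = Segmentation(
                labels=seg_df["label"].to_numpy(int),
                abs_corr=seg_df["abs_corr"].to_numpy(float),
                gfp=seg_df["gfp"].to_numpy(float),
                sfreq=config.preproc.target_hz,
                n_maps=k,
            )
            table = tr.normalized_transitions(tr.transition_counts(seg), tr.run_frequencies(seg))
            tidy = table.to_frame(map_labels=templates.labels)
            tidy.insert(0, "subject_id", rec.subject_id)
            tidy.insert(1, "group", rec.group)
            frames.append(tidy)
        pd.concat(frames, ignore_index=True).to_csv(workdir / "transitions.csv", index=False)


def _group_split(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    groups = sorted(df["group"].dropna().unique())
    if len(groups) != 2:
        raise InvalidArgumentError(f"need exactly 2 groups, found {groups}")
    return df[df["group"] == groups[0]], df[df["group"] == groups[1]]


def stage_stats(config: PipelineConfig, workdir: Path) -> dict:
    with _timed("stats"):
        alpha = config.stats.alpha
        rng_root = np.random.SeedSequence(config.seed)
        metrics = pd.read_csv(workdir / "metrics.csv")
        trans = pd.read_csv(workdir / "transitions.csv")
        summary: dict = _provenance(config)

        # --- microstate parameters: Mann-Whitney + Li-Ji/Sidak ------------
        rows = []
        wide_cols = {}
        for map_label in sorted(metrics["map"].unique()):
            for param in PARAM_COLS:
                sub = metrics[metrics["map"] == map_label]
                a, b = _group_split(sub)
                res = st.mann_whitney(a[param].to_numpy(), b[param].to_numpy())
                rows.append(
                    {
                        "test": "mann_whitney",
                        "variable": f"{param}:{map_label}",
                        "statistic": res.statistic,
                        "p": res.p,
                        "effect": res.effect,
                    }
                )
                wide_cols[f"{param}:{map_label}"] = sub.sort_values("subject_id")[param].to_numpy()
        param_df = pd.DataFrame(rows)
        X = np.column_stack([v for v in wide_cols.values() if np.std(v) > 1e-12])
        meff = st.li_ji_meff(X, alpha=alpha)
        param_df["alpha_adjusted"] = meff.alpha_adjusted
        param_df["significant"] = param_df["p"] < meff.alpha_adjusted
        param_df.to_csv(workdir / "stats_parameters.csv", index=False)
        summary["parameters_m_eff"] = meff.m_eff
        summary["parameters_alpha_adjusted"] = meff.alpha_adjusted

        # --- transitions: unpaired t tests + Li-Ji/Sidak ------------------
        rows = []
        t_cols = {}
        for (src, dst), sub in trans.groupby(["from_map", "to_map"]):
            a, b = _group_split(sub)
            va, vb = a["normalized"].to_numpy(), b["normalized"].to_numpy()
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            t_res = sps.ttest_ind(va, vb)
            sp_ = np.sqrt(((len(va) - 1) * va.std(ddof=1) ** 2 + (len(vb) - 1) * vb.std(ddof=1) ** 2)
                          / (len(va) + len(vb) - 2))
            rows.append(
                {
                    "test": "t",
                    "variable": f"transition:{src}->{dst}",
                    "statistic": float(t_res.statistic),
                    "p": float(t_res.pvalue),
                    "effect": float((va.mean() - vb.mean()) / sp_) if sp_ > 0 else np.nan,
                }
            )
            col = sub.sort_values("subject_id")["normalized"].to_numpy()
            if np.all(np.isfinite(col)):
                t_cols[f"{src}->{dst}"] = col
        trans_df = pd.DataFrame(rows)
        Xt = np.column_stack(list(t_cols.values()))
        meff_t = st.li_ji_meff(Xt, alpha=alpha)
        trans_df["alpha_adjusted"] = meff_t.alpha_adjusted
        trans_df["significant"] = trans_df["p"] < meff_t.alpha_adjusted
        trans_df.to_csv(workdir / "stats_transitions.csv", index=False)
        summary["transitions_m_eff"] = meff_t.m_eff
        summary["transitions_alpha_adjusted"] = meff_t.alpha_adjusted

        # --- TANOVA per map class on subject mean topographies ------------
        templates = _read_templates(workdir)
        recs = _load_recordings(workdir / "preprocessed")
        tanova_rows = []
        maps_by_group: dict[str, dict[str, list[np.ndarray]]] = {}
        for rec in recs:
            seg_df = pd.read_csv(workdir / "segmentations" / f"{rec.subject_id}.csv")
            labels = seg_df["label"].to_numpy(int)
            data = rec.data - rec.data.mean(axis=0, keepdims=True)
            for mi, mlab in enumerate(templates.labels):
                sel = labels == mi
                if sel.sum() < 2:
                    continue
                samples = data[:, sel]
                signs = np.sign(templates.maps[mi] @ samples)
                signs[signs == 0] = 1.0
                mean_map = (samples * signs).mean(axis=1)
                maps_by_group.setdefault(mlab, {}).setdefault(rec.group, []).append(mean_map)
        for mlab, by_group in sorted(maps_by_group.items()):
            groups = sorted(by_group)
            if len(groups) != 2:
                continue
            res = st.tanova(
                np.asarray(by_group[groups[0]]),
                np.asarray(by_group[groups[1]]),
                n_perm=config.stats.n_perm,
                seed=rng_root.spawn(1)[0],
            )
            tanova_rows.append(
                {"test": "tanova", "variable": f"map:{mlab}", "statistic": res.statistic,
                 "p": res.p}
            )
        pd.DataFrame(tanova_rows).to_csv(workdir / "stats_tanova.csv", index=False)

        headline = param_df.loc[param_df["significant"], "variable"].tolist()
        summary["significant_parameters"] = headline
        summary["significant_transitions"] = trans_df.loc[
            trans_df["significant"], "variable"
        ].tolist()
        (workdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return summary


def stage_spectrum(config: PipelineConfig, workdir: Path) -> None:
    with _timed("spectrum"):
        recs = _load_recordings(workdir / "preprocessed")
        rows = []
        for rec in recs:
            spec = sp.power_spectrum(rec)
            bands = sp.band_power(spec)
            for name, (lo, hi, power) in bands.items():
                rows.append(
                    {"subject_id": rec.subject_id, "group": rec.group, "band": name,
                     "low_hz": lo, "high_hz": hi, "power": power}
                )
        band_df = pd.DataFrame(rows)
        band_df.to_csv(workdir / "band_power.csv", index=False)
        tests = []
        for name, sub in band_df.groupby("band"):
            a, b = _group_split(sub)
            res = st.mann_whitney(a["power"].to_numpy(), b["power"].to_numpy())
            tests.append({"band": name, "U": res.statistic, "p": res.p, "cliffs_delta": res.effect})
        pd.DataFrame(tests).to_csv(workdir / "stats_bands.csv", index=False)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage in order; returns the results directory."""
    violations = validate_config(config)
    if violations:
        raise InvalidArgumentError("invalid config: " + "; ".join(violations))
    workdir = Path(out_dir)
    workdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(workdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config hash %s, seed %d", config_hash(config), config.seed)
        if config.simulation is not None and config.input_dir is None:
            stage_simulate(config, workdir)
        stage_preprocess(config, workdir)
        stage_cluster(config, workdir)
        stage_backfit(config, workdir)
        stage_transitions(config, workdir)
        stage_stats(config, workdir)
        stage_spectrum(config, workdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return workdir
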