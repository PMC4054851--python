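"""End-to-end orchestration: simulate -> call -> frequencies -> burden ->
panel -> qPCR, emitting one run directory of tabular reports plus a manifest.

Every run is reproducible from its manifest: the manifest records the full
configuration, the seed, the package version and a digest of every output
file, and identical (config, seed) pairs produce byte-identical outputs.
Per-stage random streams are derived from fixed (seed, stage) keys, so
disabling one stage never changes another stage's numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, datasets, io, qpcr as qpcr_mod
from .calling import call_cohort
from .frequency import frequency_table, sample_burden, select_high_frequency, arm_counts
from .model import CallThresholds, ConfigError
from .panel import evaluate_panel
from .simulate import ArraySimConfig, QpcrSimConfig, control_clone_ids, simulate_cohort, simulate_qpcr

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

#: Stage names in execution order, with the fixed key used to derive the
#: stage's random stream (stable even when stages are disabled).
_STAGE_KEYS = {"simulate": 0, "negatives": 1, "qpcr": 2}

DEFAULT_CONFIG: dict = {
    "stages": ["simulate", "call", "frequencies", "burden", "panel", "qpcr"],
    "array": {
        "n_samples": 23,
        "n_background_sites": 161,  # fills the 180-clone layout around the 19 annotated sites
        "background_event_prob": 0.05,
        "noise_sd": 0.25,
        "missing_rate": 0.02,
    },
    "thresholds": {"md_log_ratio": -0.58, "ad_log_ratio": 0.58, "min_valid": 4},
    "selection": {"min_count": 4},
    "burden": {"threshold": 9},
    "panel": {"negatives_n": 23, "negatives_event_prob": 0.01},
    # median tumor/normal fold change per gene (1.0 = typically unchanged) and
    # the per-sample lognormal spread of true folds around that median
    "qpcr": {
        "n_samples": 12,
        "spread_log2_sd": 1.5,
        "genes": {"LRRN1": 0.33, "GORASP1": 1.0, "IQSEC1": 1.0, "FOXP1": 1.0,
                  "GNAI2": 1.0, "FGD5": 1.0, "PLCL2": 1.0, "ALDH1L1": 0.25},
    },
}

#: qPCR subset of the cohort, stratified over stages I/II/III.
QPCR_SAMPLES = ["S01", "S02", "S03", "S04", "S08", "S09", "S10", "S11",
                "S17", "S18", "S19", "S20"]


def _merge(base: Mapping, override: Mapping | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, Mapping) and isinstance(base.get(k), Mapping) else v
    return out


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 900 + _STAGE_KEYS[stage]]))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulated_qpcr_gene(gene, median_fold, n, spread_sd, rng):
    rels = []
    for i, sample in enumerate(QPCR_SAMPLES[:n]):
        fold = float(median_fold * 2.0 ** rng.normal(0.0, spread_sd))
        cfg = QpcrSimConfig(true_fold_change=fold)
        q = simulate_qpcr(cfg, gene=gene, sample_id=sample, rng=rng)
        rels.append(qpcr_mod.relative_expression(q))
    return rels


def run_pipeline(config: Mapping | None = None, out_dir="results/run", seed: int = 0) -> dict:
    """Run the configured stages and write reports under ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    stages = list(cfg["stages"])
    unknown = set(stages) - {"simulate", "call", "frequencies", "burden", "panel", "qpcr"}
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = CallThresholds(**cfg["thresholds"])
    statuses: list[dict] = []
    summary: list[str] = []
    outputs: list[Path] = []

    sites = datasets.high_frequency_sites()
    freqs = datasets.site_frequencies()
    site_by_id = {s.clone_id: s for s in sites}

    def _array_cfg(event_prob: float, seed_key: int) -> tuple[ArraySimConfig, list[str], np.ndarray]:
        a = cfg["array"]
        n_bg = int(a["n_background_sites"])
        clone_ids = [s.clone_id for s in sites] + [f"NMA-{i:03d}" for i in range(1, n_bg + 1)]
        probs = np.concatenate([
            np.array([f.md_count / f.n_samples for f in freqs]),
            np.full(n_bg, event_prob),
        ])
        sim = ArraySimConfig(
            n_sites=len(clone_ids),
            noise_sd=float(a["noise_sd"]),
            missing_rate=float(a["missing_rate"]),
            event_prob=event_prob,
            seed=int(seed) + seed_key,
        )
        return sim, clone_ids, probs

    matrix = None
    # --- simulate + call the tumor/normal cohort ---------------------------
    if "simulate" in stages:
        sim, clone_ids, probs = _array_cfg(float(cfg["array"]["background_event_prob"]), 0)
        cohort, truth = simulate_cohort(sim, int(cfg["array"]["n_samples"]),
                                        site_probs=probs, clone_ids=clone_ids)
        io.write_call_matrix(truth, out / "truth_matrix.tsv")
        outputs.append(out / "truth_matrix.tsv")
        statuses.append({"stage": "simulate", "status": "ok", "n_samples": len(cohort)})
        if "call" in stages:
            matrix = call_cohort(cohort, th, control_clone_ids(sim.n_controls))
            io.write_call_matrix(matrix, out / "call_matrix.tsv")
            outputs.append(out / "call_matrix.tsv")
            statuses.append({"stage": "call", "status": "ok"})

    # --- frequencies / burden / panel on the called matrix -----------------
    if matrix is not None and "frequencies" in stages:
        table = frequency_table(matrix, sites)
        selected = select_high_frequency(table, int(cfg["selection"]["min_count"]))
        rows = [{"clone_id": f.clone_id, "md_count": f.md_count,
                 "n_samples": f.n_samples, "percent": f.percent} for f in table]
        pd.DataFrame(rows).to_csv(out / "frequency_table.tsv", sep="\t", index=False)
        outputs.append(out / "frequency_table.tsv")
        annotated = [site_by_id[f.clone_id] for f in selected if f.clone_id in site_by_id]
        p_count, q_count = arm_counts(annotated) if annotated else (0, 0)
        summary.append(f"high-frequency sites (>= {cfg['selection']['min_count']} MD): {len(selected)}")
        summary.append(f"annotated selected sites on 3p: {p_count}, on 3q: {q_count}")
        statuses.append({"stage": "frequencies", "status": "ok", "selected": len(selected)})

        if "burden" in stages:
            chosen = [f.clone_id for f in selected]
            burden = sample_burden(matrix, chosen, int(cfg["burden"]["threshold"]))
            pd.DataFrame([b.__dict__ for b in burden]).to_csv(out / "burden.tsv", sep="\t", index=False)
            outputs.append(out / "burden.tsv")
            n_flagged = sum(b.flagged for b in burden)
            summary.append(f"samples with > {cfg['burden']['threshold']} MD of {len(chosen)} selected sites: {n_flagged}")
            statuses.append({"stage": "burden", "status": "ok", "flagged": n_flagged})

        if "panel" in stages:
            panel = datasets.six_marker_panel()
            neg_sim, clone_ids, _ = _array_cfg(float(cfg["panel"]["negatives_event_prob"]), 7919)
            neg_cohort, _ = simulate_cohort(
                neg_sim, int(cfg["panel"]["negatives_n"]),
                site_probs=np.full(len(clone_ids), neg_sim.event_prob),
                clone_ids=clone_ids, sample_prefix="N",
            )
            negatives = call_cohort(neg_cohort, th, control_clone_ids(neg_sim.n_controls))
            metrics = evaluate_panel(matrix, negatives, panel)
            pd.DataFrame([{
                "k": panel.k, "markers": ";".join(panel.marker_clone_ids),
                "tp": metrics.tp, "fn": metrics.fn, "tn": metrics.tn, "fp": metrics.fp,
                "sensitivity": metrics.sensitivity, "specificity": metrics.specificity,
                "accuracy": metrics.accuracy, "gini": metrics.gini,
            }]).to_csv(out / "panel_metrics.tsv", sep="\t", index=False)
            outputs.append(out / "panel_metrics.tsv")
            summary.append(
                f"panel (2 of 6): sensitivity {metrics.sensitivity:.2f}, "
                f"specificity {metrics.specificity:.2f}, accuracy {metrics.accuracy:.2f}, "
                f"gini {metrics.gini:.2f}"
            )
            statuses.append({"stage": "panel", "status": "ok"})

    # --- qPCR expression ----------------------------------------------------
    if "qpcr" in stages:
        rng = _stage_rng(seed, "qpcr")
        qc = cfg["qpcr"]
        stages_by_sample = {s.sample_id: s.stage for s in datasets.study_samples()}
        rows, stat_rows = [], []
        for gene, median_fold in qc["genes"].items():
            rels = _simulated_qpcr_gene(gene, float(median_fold), int(qc["n_samples"]),
                                        float(qc["spread_log2_sd"]), rng)
            s = qpcr_mod.summarize_cohort(rels)
            rows.append({
                "gene": gene, "n": s.n, "freq_down": s.freq_down, "freq_up": s.freq_up,
                "n_down": s.n_down, "n_up": s.n_up, "median_fold": s.median_fold,
                "median_direction": s.median_direction, "r_max": s.r_max, "r_min": s.r_min,
            })
            res = qpcr_mod.stage_association(rels, stages_by_sample)
            stat_rows.append({"gene": gene, "test": res.test_name,
                              "statistic": res.statistic, "p_value": res.p_value,
                              "method_note": res.method_note})
        pd.DataFrame(rows).to_csv(out / "qpcr_summary.tsv", sep="\t", index=False)
        pd.DataFrame(stat_rows).to_csv(out / "stats.tsv", sep="\t", index=False)
        outputs.extend([out / "qpcr_summary.tsv", out / "stats.tsv"])
        statuses.append({"stage": "qpcr", "status": "ok", "genes": len(rows)})

    (out / "summary.txt").write_text("\n".join(summary) + "\n", encoding="utf-8")
    outputs.append(out / "summary.txt")
    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config": cfg,
        "stages": statuses,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
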