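"""Synthetic data generators for every input the pipeline consumes.

Three generators mirror the three assays of the study design:

* paired tumor/normal two-channel spot intensities for an array of NotI
  clones (six replicate spots each, E. coli negative-control spots, planted
  methylation/deletion and amplification/demethylation events, lognormal
  spot noise, missing spots);
* triplicate qPCR Ct values for a target and reference genes in paired
  tissues, generated by inverting the efficiency-corrected relative
  quantification formula so planted fold changes close the loop with the
  estimator;
* bisulfite-sequenced clone methylation matrices (clones x CpG positions).

Same seed + same config => bit-identical output (replayability contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import BisulfiteCloneSet, CallState, ConfigError, QpcrSampleSet

__all__ = [
    "ArraySimConfig",
    "BisulfiteSimConfig",
    "QpcrSimConfig",
    "control_clone_ids",
    "simulate_array_pair",
    "simulate_bisulfite",
    "simulate_cohort",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class ArraySimConfig:
    """Parameters of the paired tumor/normal array simulator.

    The array layout follows the study design: 180 NotI clones in six
    replicate spots plus non-human (E. coli) negative-control spots. An MD
    event multiplies the tumor-channel signal by ``md_effect`` (default 0.5,
    the simplest copy-ratio reading of a hemizygous loss or full monoallelic
    methylation); an AD event by ``ad_effect`` (default 2.0). AD events are
    rare by default, matching their "single cases" role in the study. Spot
    noise is lognormal on the signal, with a multiplicative background.
    """

    n_sites: int = 180
    n_replicates: int = 6
    n_controls: int = 6
    event_prob: float = 0.05
    ad_prob: float = 0.01
    md_effect: float = 0.5
    ad_effect: float = 2.0
    noise_sd: float = 0.25
    missing_rate: float = 0.02
    hyper_prob: float = 0.0
    hyper_gain: float = 0.5
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.0
    background_level: float = 100.0
    background_log2_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("event_prob", "ad_prob", "missing_rate", "hyper_prob", "hyper_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.md_effect < 1.0:
            raise ConfigError(f"md_effect={self.md_effect} must lie in (0, 1)")
        if self.ad_effect <= 1.0:
            raise ConfigError(f"ad_effect={self.ad_effect} must exceed 1")
        if self.noise_sd < 0 or self.background_log2_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.n_sites < 1 or self.n_replicates < 1 or self.n_controls < 0:
            raise ConfigError("array layout counts out of range")


def default_clone_ids(n_sites: int) -> list[str]:
    return [f"NMA-{i:03d}" for i in range(1, n_sites + 1)]


def control_clone_ids(n_controls: int) -> list[str]:
    """Clone ids of the non-human (E. coli DNA) negative-control spots."""
    return [f"CTRL-ECOLI-{i:02d}" for i in range(1, n_controls + 1)]


def _states(rng: np.random.Generator, probs: np.ndarray, ad_prob: float) -> np.ndarray:
    u = rng.random(len(probs))
    states = np.full(len(probs), CallState.RET.value, dtype=object)
    states[u < probs + ad_prob] = CallState.AD.value
    states[u < probs] = CallState.MD.value
    return states


def simulate_array_pair(
    cfg: ArraySimConfig,
    *,
    rng: np.random.Generator | None = None,
    site_probs=None,
    clone_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate one tumor/normal hybridization with planted events.

    Returns ``(spots, truth)``: a spot table (clone_id, replicate, channel,
    foreground, background, flag) and the planted per-site state (a Series
    over the non-control clones). ``site_probs`` overrides the scalar
    ``event_prob`` with a per-site MD probability vector.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, reps = cfg.n_sites, cfg.n_replicates
    if site_probs is None:
        probs = np.full(n, cfg.event_prob)
    else:
        probs = np.asarray(site_probs, float)
        if probs.shape != (n,):
            raise ConfigError(f"site_probs must have length n_sites={n}")
        if ((probs < 0) | (probs > 1)).any():
            raise ConfigError("site_probs must lie in [0, 1]")
    clones = list(clone_ids) if clone_ids is not None else default_clone_ids(n)
    if len(clones) != n:
        raise ConfigError(f"clone_ids must have length n_sites={n}")

    states = _states(rng, probs, cfg.ad_prob)
    effect = np.ones(n)
    effect[states == CallState.MD.value] = cfg.md_effect
    effect[states == CallState.AD.value] = cfg.ad_effect
    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)

    all_ids = clones + control_clone_ids(cfg.n_controls)
    total = len(all_ids)
    # control spots carry no human signal: foreground == background
    signal = np.concatenate([baseline, np.zeros(cfg.n_controls)])
    chan_effect = {
        "normal": np.ones(total),
        "tumor": np.concatenate([effect, np.ones(cfg.n_controls)]),
    }
    frames = []
    for channel in ("tumor", "normal"):
        bg = cfg.background_level * 2.0 ** rng.normal(0.0, cfg.background_log2_sd, (total, reps))
        noise = 2.0 ** rng.normal(0.0, cfg.noise_sd, (total, reps))
        fg = bg + (signal * chan_effect[channel])[:, None] * noise
        bad = rng.random((total, reps)) < cfg.missing_rate
        frames.append(
            pd.DataFrame(
                {
                    "clone_id": np.repeat(all_ids, reps),
                    "replicate": np.tile(np.arange(1, reps + 1), total),
                    "channel": channel,
                    "foreground": fg.ravel(),
                    "background": bg.ravel(),
                    "flag": np.where(bad.ravel(), "bad", "ok"),
                }
            )
        )
    spots = pd.concat(frames, ignore_index=True)
    truth = pd.Series(states, index=pd.Index(clones, name="clone_id"), name="state")
    return spots, truth


def simulate_cohort(
    cfg: ArraySimConfig,
    n_samples: int,
    *,
    site_probs=None,
    clone_ids: list[str] | None = None,
    sample_prefix: str = "S",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate ``n_samples`` independent tumor/normal pairs.

    Returns ``(cohort, truth)`` where ``cohort`` maps sample id to its spot
    table and ``truth`` is the planted sites x samples state matrix. Events
    are drawn independently across sites and samples; the study's marginal
    frequencies are the only structure emulated by default. Setting
    ``hyper_prob`` > 0 adds a per-sample "hypermethylator" latent factor:
    with that probability a sample's per-site event probabilities are
    raised to p + (1-p)*hyper_gain, producing the co-occurring high-burden
    samples seen in real cohorts.
    """
    if n_samples < 0:
        raise ConfigError("n_samples must be >= 0")
    width = max(2, len(str(n_samples)))
    ids = [f"{sample_prefix}{i:0{width}d}" for i in range(1, n_samples + 1)]
    cohort: dict[str, pd.DataFrame] = {}
    columns = {}
    base_probs = None if site_probs is None else np.asarray(site_probs, float)
    for i, sample in enumerate(ids):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        probs = np.full(cfg.n_sites, cfg.event_prob) if base_probs is None else base_probs
        if cfg.hyper_prob > 0 and rng.random() < cfg.hyper_prob:
            probs = probs + (1.0 - probs) * cfg.hyper_gain
        spots, truth = simulate_array_pair(cfg, rng=rng, site_probs=probs, clone_ids=clone_ids)
        cohort[sample] = spots
        columns[sample] = truth
    n = cfg.n_sites
    index = pd.Index(
        list(clone_ids) if clone_ids is not None else default_clone_ids(n), name="clone_id"
    )
    truth_matrix = pd.DataFrame(columns, index=index, dtype=object) if ids else pd.DataFrame(index=index)
    return cohort, truth_matrix


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrSimConfig:
    """Generative model for paired-tissue qPCR, the exact inverse of the
    efficiency-corrected relative-expression estimator.

    A true tumor/normal fold change ``f`` of the target shifts the tumor
    target Ct by ``-log2(f) / log2(1 + E_tar)`` cycles; reference genes are
    flat across tissues. Replicate noise is Gaussian on Ct.
    """

    true_fold_change: float = 1.0
    base_ct: float = 25.0
    ref_base_ct: float = 20.0
    efficiency_tar: float = 0.95
    efficiency_ref: float = 0.95
    ct_replicate_sd: float = 0.15
    n_replicates: int = 3
    references: tuple[str, ...] = ("GUSB", "RPN1")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fold_change <= 0:
            raise ConfigError("true_fold_change must be positive")
        for e in (self.efficiency_tar, self.efficiency_ref):
            if not 0 < e <= 1:
                raise ConfigError(f"efficiency {e} outside (0, 1]")
        if self.ct_replicate_sd < 0:
            raise ConfigError("ct_replicate_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


def simulate_qpcr(
    cfg: QpcrSimConfig,
    *,
    gene: str = "GENE",
    sample_id: str = "S01",
    rng: np.random.Generator | None = None,
) -> QpcrSampleSet:
    """Simulate triplicate Ct values for one paired tumor/normal sample."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    reps = cfg.n_replicates

    def noisy(mean: float) -> np.ndarray:
        return mean + rng.normal(0.0, cfg.ct_replicate_sd, reps)

    shift = -np.log2(cfg.true_fold_change) / np.log2(1.0 + cfg.efficiency_tar)
    return QpcrSampleSet(
        gene=gene,
        sample_id=sample_id,
        ct_tar_normal=noisy(cfg.base_ct),
        ct_tar_tumor=noisy(cfg.base_ct + shift),
        ct_ref_normal={r: noisy(cfg.ref_base_ct) for r in cfg.references},
        ct_ref_tumor={r: noisy(cfg.ref_base_ct) for r in cfg.references},
        e_tar=cfg.efficiency_tar,
        e_ref={r: cfg.efficiency_ref for r in cfg.references},
    )


# ---------------------------------------------------------------------------
# bisulfite clone matrices


@dataclass(frozen=True)
class BisulfiteSimConfig:
    """Generator for bisulfite-sequenced clone methylation matrices.

    Defaults emulate the study's amplicon layout: 24 CpG dinucleotides, 7
    sequenced clones, with the two CpGs of the NotI recognition site at
    positions 13-14 (a synthetic placement; the assay only requires that the
    flagged subset lie inside the amplicon). Each clone x CpG methylation is
    an independent Bernoulli draw with per-CpG probability.
    """

    n_clones: int = 7
    n_cpg: int = 24
    per_cpg_meth_prob: tuple[float, ...] | float = 0.85
    noti_cpg_indices: tuple[int, ...] = (13, 14)
    seed: int = 0

    def probs(self) -> np.ndarray:
        if np.isscalar(self.per_cpg_meth_prob):
            p = np.full(self.n_cpg, float(self.per_cpg_meth_prob))
        else:
            p = np.asarray(self.per_cpg_meth_prob, float)
        if p.shape != (self.n_cpg,):
            raise ConfigError(
                f"per_cpg_meth_prob length {p.shape} does not match n_cpg={self.n_cpg}"
            )
        if ((p < 0) | (p > 1)).any():
            raise ConfigError("methylation probabilities must lie in [0, 1]")
        return p

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.n_cpg < 1:
            raise ConfigError("n_clones and n_cpg must be >= 1")
        self.probs()
        if any(not 1 <= i <= self.n_cpg for i in self.noti_cpg_indices):
            raise ConfigError("noti_cpg_indices outside 1..n_cpg")


def simulate_bisulfite(
    cfg: BisulfiteSimConfig,
    *,
    gene: str = "GENE",
    sample_id: str = "S01",
    rng: np.random.Generator | None = None,
) -> BisulfiteCloneSet:
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    matrix = rng.random((cfg.n_clones, cfg.n_cpg)) < cfg.probs()
    return BisulfiteCloneSet(
        gene=gene, sample_id=sample_id, matrix=matrix, noti_cpg_indices=cfg.noti_cpg_indices
    )
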