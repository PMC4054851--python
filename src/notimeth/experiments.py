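"""Reusable in-silico experiments over the full pipeline.

These functions tie the synthetic generators to the analysis chain so that
planted-parameter recovery can be measured reproducibly from a single seed.
They are used by the validation suite and the reproduction script alike.
"""

from __future__ import annotations

import numpy as np

from . import datasets
from .calling import call_pair
from .model import CallState, CallThresholds
from .simulate import ArraySimConfig, control_clone_ids, simulate_array_pair

__all__ = ["planted_site_recovery"]


def planted_site_recovery(
    seed: int,
    n_pairs: int = 5000,
    clone_id: str = "NL1-CJ4R (C)",
    thresholds: CallThresholds = CallThresholds(),
    array_config: ArraySimConfig | None = None,
) -> dict:
    """Recover one site's planted MD frequency through the full pipeline.

    Simulates ``n_pairs`` tumor/normal hybridizations of the default array
    layout, with the target site's event probability set to its printed MD
    frequency (and the remaining high-frequency sites at theirs, background
    sites at the default rate), then aggregates, normalizes and calls every
    pair and reports the percentage of pairs called MD at the target site.

    Returns a dict with ``planted_percent``, ``called_percent``,
    ``planted_prob``, ``n_pairs`` and the per-pair call breakdown.
    """
    freqs = datasets.site_frequencies()
    by_id = {f.clone_id: f for f in freqs}
    if clone_id not in by_id:
        raise KeyError(f"no printed frequency for clone {clone_id!r}")
    base = ArraySimConfig(seed=int(seed)) if array_config is None else array_config
    n_named = len(freqs)
    if base.n_sites < n_named:
        raise ValueError(f"array must hold at least the {n_named} annotated sites")
    clone_ids = [f.clone_id for f in freqs] + [
        f"NMA-{i:03d}" for i in range(1, base.n_sites - n_named + 1)
    ]
    probs = np.concatenate([
        np.array([f.md_count / f.n_samples for f in freqs]),
        np.full(base.n_sites - n_named, base.event_prob),
    ])
    controls = control_clone_ids(base.n_controls)
    counts = {s.value: 0 for s in CallState}
    root = np.random.SeedSequence([int(seed), 424242])
    for child in root.spawn(n_pairs):
        rng = np.random.default_rng(child)
        spots, _ = simulate_array_pair(base, rng=rng, site_probs=probs, clone_ids=clone_ids)
        calls = call_pair(spots, thresholds, controls)
        counts[calls[clone_id]] += 1
    called = 100.0 * counts[CallState.MD.value] / n_pairs
    target = by_id[clone_id]
    return {
        "clone_id": clone_id,
        "planted_prob": target.md_count / target.n_samples,
        "planted_percent": target.percent,
        "called_percent": called,
        "called_percent_rounded": int(np.floor(called + 0.5)),
        "n_pairs": n_pairs,
        "call_counts": counts,
    }
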