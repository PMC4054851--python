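import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notimeth.calling import (
    aggregate_replicates,
    call_cohort,
    call_pair,
    call_state,
    normalize_pair,
    pair_signals,
)
from notimeth.model import (
    CallState,
    CallThresholds,
    NormalizationError,
    StructuralError,
)
from notimeth.simulate import ArraySimConfig, control_clone_ids, simulate_cohort


def _spots(nets, flags=None, channel="tumor", clone="C1"):
    flags = flags or ["ok"] * len(nets)
    return pd.DataFrame(
        {
            "clone_id": clone,
            "replicate": range(1, len(nets) + 1),
            "channel": channel,
            "foreground": [n + 100.0 for n in nets],
            "background": 100.0,
            "flag": flags,
        }
    )


class TestAggregateReplicates:
    def test_median_of_six_replicates(self):
        spots = _spots([900, 920, 880, 910, 890, 905])
        assert aggregate_replicates(spots) == 902.5

    def test_too_few_unflagged_spots_is_no_data(self):
        spots = _spots([900, 920, 880, 910, 890, 905],
                       flags=["ok", "ok", "ok", "bad", "bad", "bad"])
        assert aggregate_replicates(spots, min_valid=4) is None

    def test_zero_records_is_no_data_not_an_exception(self):
        assert aggregate_replicates(_spots([]), min_valid=1) is None

    def test_net_clamps_to_zero_when_background_exceeds_foreground(self):
        spots = _spots([0.0] * 6)
        spots["foreground"] = 80.0  # background 100 -> net 0
        assert aggregate_replicates(spots) == 0.0


def _signals(log_ratios):
    return pd.DataFrame(
        {
            "net_tumor": 1.0, "net_normal": 1.0, "n_tumor": 6, "n_normal": 6,
            "log_ratio": log_ratios,
        },
        index=pd.Index([f"C{i}" for i in range(len(log_ratios))], name="clone_id"),
    )


class TestNormalizePair:
    def test_already_centred_ratios_are_unchanged(self):
        out = normalize_pair(_signals([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(out["log_ratio"], [-1.0, 0.0, 1.0])

    def test_constant_offset_is_removed(self):
        out = normalize_pair(_signals([0.3] * 5))
        np.testing.assert_allclose(out["log_ratio"], 0.0)

    def test_no_data_sites_are_preserved_and_excluded_from_median(self):
        values = [0.3] * 9 + [np.nan]
        out = normalize_pair(_signals(values))
        assert np.isnan(out["log_ratio"].iloc[-1])
        np.testing.assert_allclose(out["log_ratio"].iloc[:9], 0.0)

    def test_controls_are_excluded_from_the_median(self):
        sig = _signals([0.0, 0.0, 0.0, 5.0, 5.0])
        sig.index = pd.Index(["A", "B", "C", "CTRL-1", "CTRL-2"], name="clone_id")
        out = normalize_pair(sig, control_ids=["CTRL-1", "CTRL-2"])
        np.testing.assert_allclose(out["log_ratio"].iloc[:3], 0.0)

    def test_no_defined_ratios_is_an_error(self):
        with pytest.raises(NormalizationError):
            normalize_pair(_signals([np.nan, np.nan]))


class TestCallState:
    @pytest.mark.parametrize(
        "log_ratio,expected",
        [
            (-1.0, CallState.MD),
            (1.0, CallState.AD),
            (-0.58, CallState.MD),   # boundary resolves to the event state
            (0.58, CallState.AD),
            (-0.57, CallState.RET),
            (0.0, CallState.RET),
            (float("nan"), CallState.NODATA),
            (None, CallState.NODATA),
            (float("-inf"), CallState.MD),
        ],
    )
    def test_thresholding(self, log_ratio, expected):
        assert call_state(log_ratio) is expected

    @given(st.floats(-4, 4), st.floats(-4, 4))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_log_ratio(self, a, b):
        """Lowering the tumor signal can only move a call toward MD."""
        order = {CallState.MD: 0, CallState.RET: 1, CallState.AD: 2}
        lo, hi = min(a, b), max(a, b)
        assert order[call_state(lo)] <= order[call_state(hi)]


class TestFullChain:
    def _cohort(self, **kw):
        defaults = dict(n_sites=40, seed=11)
        defaults.update(kw)
        cfg = ArraySimConfig(**defaults)
        probs = np.zeros(cfg.n_sites)
        probs[:8] = [0.57, 0.43, 0.43, 0.35, 0.35, 0.30, 0.22, 0.17]
        cohort, truth = simulate_cohort(cfg, 6, site_probs=probs)
        return cfg, cohort, truth

    def test_noise_free_calls_equal_planted_truth(self):
        cfg, cohort, truth = self._cohort(noise_sd=0.0, missing_rate=0.0,
                                          background_log2_sd=0.0)
        matrix = call_cohort(cohort, control_ids=control_clone_ids(cfg.n_controls))
        pd.testing.assert_frame_equal(matrix, truth, check_names=False)

    def test_all_sites_altered_is_callable_without_centering(self):
        """A genome-wide alteration is only identifiable on the uncentred
        path: per-pair median centering would absorb it."""
        cfg = ArraySimConfig(n_sites=20, noise_sd=0.0, missing_rate=0.0,
                             event_prob=1.0, background_log2_sd=0.0, seed=12)
        cohort, truth = simulate_cohort(cfg, 3)
        matrix = call_cohort(cohort, control_ids=control_clone_ids(cfg.n_controls),
                             normalize=False)
        assert (matrix == CallState.MD.value).all().all()

    def test_scale_invariance_of_calls(self):
        cfg, cohort, _ = self._cohort()
        controls = control_clone_ids(cfg.n_controls)
        base = call_cohort(cohort, control_ids=controls)
        scaled = {
            s: spots.assign(foreground=spots.foreground * 3.7,
                            background=spots.background * 3.7)
            for s, spots in cohort.items()
        }
        pd.testing.assert_frame_equal(call_cohort(scaled, control_ids=controls), base)

    def test_single_channel_imbalance_is_absorbed_by_normalization(self):
        cfg, cohort, _ = self._cohort()
        controls = control_clone_ids(cfg.n_controls)
        base = call_cohort(cohort, control_ids=controls)
        skewed = {}
        for s, spots in cohort.items():
            tumor = spots["channel"] == "tumor"
            spots = spots.copy()
            spots.loc[tumor, ["foreground", "background"]] *= 1.8
            skewed[s] = spots
        pd.testing.assert_frame_equal(call_cohort(skewed, control_ids=controls), base)

    def test_missing_spots_below_min_valid_become_no_data(self):
        cfg = ArraySimConfig(n_sites=5, seed=13)
        cohort, _ = simulate_cohort(cfg, 1)
        spots = next(iter(cohort.values()))
        # flag out all tumor replicates of the first clone
        clone = spots["clone_id"].iloc[0]
        mask = (spots["clone_id"] == clone) & (spots["channel"] == "tumor")
        spots.loc[mask, "flag"] = "bad"
        calls = call_pair(spots, control_ids=control_clone_ids(cfg.n_controls))
        assert calls[clone] == CallState.NODATA.value

    def test_inconsistent_clone_sets_raise_structural_error(self):
        cfg, cohort, _ = self._cohort()
        items = list(cohort.items())
        broken = dict(items)
        s, spots = items[1]
        broken[s] = spots[spots["clone_id"] != "NMA-001"]
        with pytest.raises(StructuralError, match="NMA-001"):
            call_cohort(broken, control_ids=control_clone_ids(cfg.n_controls))
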