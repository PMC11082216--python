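import numpy as np
import pandas as pd
import pytest

from cdgsensor import (
    CellTrack,
    DynamicsSpec,
    FilterConfig,
    align_to_minimum,
    classify_high_low,
    filter_pairs,
    gen_lineage_tracks,
    pair_and_trim,
)
from cdgsensor.errors import MalformedLineageError, TieBreakWarning


def _track(cid, parent, lengths, fitc=None, t0_frame=0, dt=5.0):
    n = len(lengths)
    return CellTrack(
        cell_id=cid,
        parent_id=parent,
        data=pd.DataFrame({
            "frame": t0_frame + np.arange(n),
            "time_min": (t0_frame + np.arange(n)) * dt,
            "length_um": np.asarray(lengths, dtype=float),
            "fitc_mean": np.asarray(fitc, dtype=float) if fitc is not None
            else np.full(n, 100.0),
        }),
    )


def _growing(n, l0=2.0, rate=0.04):
    return l0 * np.exp(rate * np.arange(n))


class TestPairAndTrim:
    def test_trims_to_shorter_sister(self):
        mother = _track("m", None, _growing(5))
        a = _track("m.0", "m", _growing(10), t0_frame=5)
        b = _track("m.1", "m", _growing(15), t0_frame=5)
        pairs = pair_and_trim([mother, a, b])
        assert len(pairs) == 1
        assert pairs[0].trimmed_length == 10
        assert pairs[0].track_b.n_frames == 10
        assert pairs[0].mother_final_length == mother.final_length
        # retained frames are verbatim copies, no interpolation
        assert np.array_equal(pairs[0].track_b.data["length_um"],
                              b.data["length_um"].iloc[:10])

    def test_singleton_child_yields_no_pair(self):
        mother = _track("m", None, _growing(5))
        only = _track("m.0", "m", _growing(8), t0_frame=5)
        assert pair_and_trim([mother, only]) == []

    def test_three_children_rejected(self):
        tracks = [_track(f"m.{i}", "m", _growing(6)) for i in range(3)]
        with pytest.raises(MalformedLineageError):
            pair_and_trim(tracks)

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_full_binary_lineage_pair_count(self, depth):
        """A complete lineage of the given depth contains 2^depth - 1
        divisions with both daughters tracked."""
        tracks, _ = gen_lineage_tracks(depth, seed=0)
        assert len(pair_and_trim(tracks)) == 2**depth - 1


class TestFilterPairs:
    def _pair(self, n_frames, jump=None, birth_sum_factor=1.0):
        """Pair with 4%/frame growth; ``jump=(frame, size)`` replaces the
        relative change into that frame with exactly ``size``."""
        mother_len = 4.0
        factors = np.full(n_frames - 1, 1.04)
        if jump is not None:
            frame, size = jump
            factors[frame - 1] = 1.0 + size
        la = mother_len / 2 * birth_sum_factor * np.concatenate(
            [[1.0], np.cumprod(factors)])
        lb = _growing(n_frames, l0=mother_len / 2)
        mother = _track("m", None, np.full(3, mother_len))
        a = _track("m.0", "m", la, t0_frame=3)
        b = _track("m.1", "m", lb, t0_frame=3)
        return pair_and_trim([mother, a, b])[0]

    def test_minimum_frames_species_presets(self):
        """11 frames fails the 12-frame C. crescentus minimum; 8 frames
        passes the 8-frame P. aeruginosa minimum."""
        pair11 = self._pair(11)
        kept, rej = filter_pairs([pair11], FilterConfig.caulobacter())
        assert not kept and rej[0][1] == ["short_track"]
        pair8 = self._pair(8)
        kept, rej = filter_pairs([pair8], FilterConfig.pseudomonas())
        assert len(kept) == 1

    def test_jump_threshold_differs_by_species(self):
        """A +9% single-frame length jump violates the 8% C. crescentus limit
        but not the 12% P. aeruginosa limit."""
        pair = self._pair(14, jump=(7, 0.09))
        kept, rej = filter_pairs([pair], FilterConfig.caulobacter())
        assert not kept and "length_jump" in rej[0][1]
        kept, _ = filter_pairs([self._pair(14, jump=(7, 0.09))],
                               FilterConfig.pseudomonas())
        assert len(kept) == 1

    def test_division_consistency_thresholds(self):
        """Summed birth lengths 25% above the mother's final length are
        rejected (>20%); 15% above are retained."""
        bad = self._pair(14, birth_sum_factor=1.5)  # sum = 1.25 x mother
        kept, rej = filter_pairs([bad], FilterConfig.caulobacter())
        assert not kept and "division_inconsistent" in rej[0][1]
        ok = self._pair(14, birth_sum_factor=1.3)  # sum = 1.15 x mother
        kept, _ = filter_pairs([ok], FilterConfig.caulobacter())
        assert len(kept) == 1

    def test_missing_mother_skips_rule_with_warning(self):
        a = _track("m.0", "m", _growing(14))
        b = _track("m.1", "m", _growing(14))
        pair = pair_and_trim([a, b])[0]
        assert pair.mother_final_length is None
        with pytest.warns(UserWarning, match="division-consistency"):
            kept, _ = filter_pairs([pair], FilterConfig.caulobacter())
        assert len(kept) == 1

    def test_idempotent_order_independent_monotone(self):
        tracks, _ = gen_lineage_tracks(
            3, error_rates={"jump_prob": 0.08}, seed=21)
        pairs = pair_and_trim(tracks)
        cfg = FilterConfig.caulobacter()
        kept1, _ = filter_pairs(pairs, cfg)
        kept2, _ = filter_pairs(kept1, cfg)  # idempotent
        assert [id(p) for p in kept1] == [id(p) for p in kept2]
        kept_rev, _ = filter_pairs(pairs[::-1], cfg)  # order-independent set
        assert {id(p) for p in kept_rev} == {id(p) for p in kept1}
        relaxed = FilterConfig(min_frames=2, jump_decrease_max=0.5,
                               jump_increase_max=0.5, division_decrease_max=0.5,
                               division_increase_max=0.9)
        kept_relaxed, _ = filter_pairs(pairs, relaxed)
        assert {id(p) for p in kept1} <= {id(p) for p in kept_relaxed}


class TestClassifyHighLow:
    def test_greater_mean_is_high(self):
        a = _track("a", "m", _growing(5), fitc=np.full(5, 5.0))
        b = _track("b", "m", _growing(5), fitc=np.full(5, 3.0))
        pair = pair_and_trim([a, b])[0]
        out = classify_high_low(pair)
        assert out["high"] == "a" and out["low"] == "b"
        assert out["mean_high"] == 5.0 and out["mean_low"] == 3.0

    def test_tie_breaks_lexicographically_with_warning(self):
        a = _track("a", "m", _growing(5))
        b = _track("b", "m", _growing(5))
        pair = pair_and_trim([a, b])[0]
        with pytest.warns(TieBreakWarning):
            out = classify_high_low(pair)
        assert out["high"] == "a"

    def test_label_accuracy_on_generated_lineages(self):
        """With 10% intensity noise, the lifetime-mean classifier recovers at
        least 95% of the generator's ground-truth identities."""
        correct = total = 0
        for seed in range(5):
            tracks, truth = gen_lineage_tracks(
                3, error_rates={"intensity_noise_sd": 0.10}, seed=seed)
            labels = dict(zip(truth["cell_id"], truth["label"]))
            for pair in pair_and_trim(tracks):
                out = classify_high_low(pair)
                total += 1
                correct += labels[out["high"]] == "high" and labels[out["low"]] == "low"
        assert total >= 30
        assert correct / total >= 0.95


class TestAlignToMinimum:
    def test_monotone_decreasing_anchors_last_frame(self):
        t = _track("a", None, _growing(6), fitc=np.linspace(10, 1, 6))
        long, _ = align_to_minimum([t])
        assert long["rel_time_min"].iloc[-1] == 0.0
        assert (long["rel_time_min"] <= 0).all()

    def test_v_shape_anchors_vertex(self):
        fitc = [5, 3, 1, 3, 5]
        t = _track("a", None, _growing(5), fitc=fitc)
        long, _ = align_to_minimum([t])
        assert long.loc[long["rel_time_min"] == 0.0, "fitc_mean"].iloc[0] == 1

    def test_trough_width_recovered_from_overlay(self):
        """Mean aligned trace of generated low-state cells recovers the true
        20-min trough width to within one frame interval."""
        dyn = DynamicsSpec(trough_duration=20.0)
        tracks, truth = gen_lineage_tracks(3, dynamics=dyn, seed=2)
        low_ids = set(truth.loc[truth["label"] == "low", "cell_id"])
        low_tracks = [t for t in tracks if t.cell_id in low_ids]
        _, summary = align_to_minimum(low_tracks)
        mid = (dyn.high_level + dyn.low_level) / 2
        below = summary.loc[summary["mean"] < mid, "rel_time_min"]
        width = below.max() - below.min()
        assert abs(width - dyn.trough_duration) <= 5.0 + 1e-9
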