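"""Respiratory gating and 25-phase ECG binning, checked against brute force."""

import numpy as np
import pytest

from rtcine import physio
from rtcine.binning import (
    BinConfig,
    bin_series,
    estimate_mean_rr,
    gate_frames,
    phase_index,
    phase_width,
    select_representative,
)
from rtcine.core import RTSeries
from rtcine.phantom import simulate_acquisition

from conftest import make_frame, make_phantom


def brute_force_bin(series, config):
    """Independent oracle: per bin, exhaustive filter-then-argmin over all frames."""
    w = config.mean_rr / config.n_phases
    out = []
    for sl in series.frames:
        chosen = []
        for k in range(config.n_phases):
            cands = [
                f
                for f in sl
                if k * w <= f.trigger_time < (k + 1) * w and f.trigger_time < config.mean_rr
            ]
            gated = [f for f in cands if f.bellows < config.gate_threshold]
            pool = gated if gated else cands
            best = min(
                pool, key=lambda f: (abs(f.bellows - config.median_target), f.acq_time)
            )
            chosen.append(best)
        out.append(chosen)
    return out


class TestPhaseArithmetic:
    @pytest.mark.parametrize(
        "mean_rr,n,expected",
        [(700.0, 25, 28.0), (25.0, 25, 1.0), (747.0, 25, 29.88)],
    )
    def test_phase_width_is_mean_rr_over_phases(self, mean_rr, n, expected):
        assert phase_width(BinConfig(mean_rr=mean_rr, n_phases=n)) == pytest.approx(expected)

    def test_half_open_bin_edges(self):
        cfg = BinConfig(mean_rr=700.0)
        assert phase_index(0.0, cfg) == 0
        assert phase_index(28.0, cfg) == 1  # lower edge of the next bin
        assert phase_index(699.9, cfg) == 24
        assert phase_index(700.0, cfg) is None  # long-beat frame
        assert phase_index(1000.0, cfg) is None

    def test_negative_trigger_errors(self):
        with pytest.raises(ValueError):
            phase_index(-1.0, BinConfig(mean_rr=700.0))


class TestGate:
    def test_strict_inequality_at_threshold(self):
        frames = [make_frame(bellows=b) for b in (500.0, 1999.0, 2000.0, 3500.0)]
        kept = gate_frames(frames, BinConfig(mean_rr=750.0))
        assert [f.bellows for f in kept] == [500.0, 1999.0]

    def test_all_above_threshold_gives_empty(self):
        frames = [make_frame(bellows=b) for b in (2000.0, 3000.0)]
        assert gate_frames(frames, BinConfig(mean_rr=750.0)) == []

    def test_unset_bellows_errors(self):
        with pytest.raises(ValueError, match="bellows"):
            gate_frames([make_frame()], BinConfig(mean_rr=750.0))

    def test_uniform_bellows_all_retained_below_gate(self):
        rng = np.random.default_rng(7)
        frames = [make_frame(bellows=b) for b in rng.uniform(0, 4000, 1000)]
        kept = gate_frames(frames, BinConfig(mean_rr=750.0))
        assert max(f.bellows for f in kept) < 2000.0


class TestRepresentative:
    def test_closest_to_median_target_wins(self):
        frames = [make_frame(bellows=b, acq=i) for i, b in enumerate((400.0, 1000.0, 1600.0))]
        chosen = select_representative(frames, BinConfig(mean_rr=750.0))
        assert chosen.bellows == 1000.0

    def test_single_candidate_returned(self):
        f = make_frame(bellows=3.0)
        assert select_representative([f], BinConfig(mean_rr=750.0)) is f

    def test_equidistant_tie_goes_to_earliest_acq_time(self):
        a = make_frame(bellows=900.0, acq=10.0)
        b = make_frame(bellows=1100.0, acq=5.0)
        cfg = BinConfig(mean_rr=750.0)
        for order in ([a, b], [b, a]):
            assert select_representative(order, cfg) is b

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            select_representative([], BinConfig(mean_rr=750.0))


class TestBinSeries:
    def test_phantom_run_fills_25_bins_per_slice(self, small_run):
        cfg, series, _, _ = small_run
        stack = bin_series(series, BinConfig(mean_rr=cfg.mean_rr_ms))
        assert stack.n_phases == 25
        assert all(len(sl) == 25 for sl in stack.frames)
        stack.validate()

    def test_matches_brute_force_oracle(self, small_run):
        cfg, series, _, _ = small_run
        bconf = BinConfig(mean_rr=cfg.mean_rr_ms)
        stack = bin_series(series, bconf)
        oracle = brute_force_bin(series, bconf)
        for sl_fast, sl_oracle in zip(stack.frames, oracle):
            for f_fast, f_oracle in zip(sl_fast, sl_oracle):
                assert f_fast is f_oracle

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_across_seeds(self, seed):
        cfg = make_phantom(seed=seed, tiny=True, duration_s=10.0)
        series, trace, _ = simulate_acquisition(cfg)
        physio.assign_bellows_to_frames(physio.preprocess_trace(trace), series)
        bconf = BinConfig(mean_rr=cfg.mean_rr_ms)
        stack = bin_series(series, bconf)
        oracle = brute_force_bin(series, bconf)
        assert all(
            f_fast is f_oracle
            for sl_f, sl_o in zip(stack.frames, oracle)
            for f_fast, f_oracle in zip(sl_f, sl_o)
        )

    def test_single_phase_reduces_to_global_best(self, small_run):
        cfg, series, _, _ = small_run
        stack = bin_series(series, BinConfig(mean_rr=cfg.mean_rr_ms, n_phases=1))
        for sl_in, sl_out in zip(series.frames, stack.frames):
            pool = [f for f in sl_in if f.trigger_time < cfg.mean_rr_ms and f.bellows < 2000.0]
            best = min(pool, key=lambda f: (abs(f.bellows - 1000.0), f.acq_time))
            assert sl_out[0] is best

    def test_deterministic(self, small_run):
        cfg, series, _, _ = small_run
        bconf = BinConfig(mean_rr=cfg.mean_rr_ms)
        s1 = bin_series(series, bconf)
        s2 = bin_series(series, bconf)
        for sl1, sl2 in zip(s1.frames, s2.frames):
            assert all(f1 is f2 for f1, f2 in zip(sl1, sl2))

    def test_gate_soundness_of_unflagged_bins(self, small_run):
        cfg, series, _, _ = small_run
        stack = bin_series(series, BinConfig(mean_rr=cfg.mean_rr_ms))
        for sl, flags in zip(stack.frames, stack.fallback_flags):
            for f, flagged in zip(sl, flags):
                if not flagged:
                    assert f.bellows < 2000.0

    def test_fallback_flags_and_disabled_fallback(self):
        """A phase with only above-gate frames is flagged, or errors when disallowed."""
        frames = [
            make_frame(bellows=2500.0, trigger=5.0, acq=0.0),
            make_frame(bellows=500.0, trigger=55.0, acq=33.0),
        ]
        series = RTSeries(frames=[frames])
        cfg = BinConfig(mean_rr=100.0, n_phases=2)
        stack = bin_series(series, cfg)
        assert stack.fallback_flags[0] == [True, False]
        with pytest.raises(ValueError, match="gate"):
            bin_series(series, BinConfig(mean_rr=100.0, n_phases=2, allow_fallback=False))

    def test_uncovered_phase_errors(self):
        series = RTSeries(frames=[[make_frame(bellows=500.0, trigger=5.0, acq=0.0)]])
        with pytest.raises(ValueError, match="insufficient coverage"):
            bin_series(series, BinConfig(mean_rr=100.0, n_phases=2))

    def test_longer_acquisitions_need_fewer_fallbacks(self):
        """Coverage law: expected unflagged fraction grows with duration."""
        def unflagged_fraction(duration, seed):
            cfg = make_phantom(
                seed=seed, tiny=True, duration_s=duration, bellows_noise_sd_au=150.0
            )
            series, trace, _ = simulate_acquisition(cfg)
            physio.assign_bellows_to_frames(physio.preprocess_trace(trace), series)
            stack = bin_series(series, BinConfig(mean_rr=cfg.mean_rr_ms))
            flags = [f for sl in stack.fallback_flags for f in sl]
            return 1.0 - sum(flags) / len(flags)

        short = np.mean([unflagged_fraction(10.0, s) for s in range(20)])
        long = np.mean([unflagged_fraction(20.0, s) for s in range(20)])
        assert long >= short


def test_estimate_mean_rr_from_trigger_resets(small_run):
    cfg, series, _, _ = small_run
    est = estimate_mean_rr(series)
    assert est == pytest.approx(cfg.mean_rr_ms, rel=0.02)
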