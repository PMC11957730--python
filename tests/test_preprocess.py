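import numpy as np
import pytest

from erpmvpa.io import EpochSet, ParameterError
from erpmvpa.preprocess import (
    bandpass,
    bandpass_array,
    baseline_correct,
    bootstrap_mean_ci,
    epoch,
    exclude_participants,
    grand_mean_ci,
    pool_electrodes,
)
from erpmvpa.simulate import simulate_epochs

SRATE = 250.0


def _tone(freq, dur=60.0, srate=SRATE):
    t = np.arange(int(dur * srate)) / srate
    return np.sin(2 * np.pi * freq * t)[None, :]


def _gain_db(freq):
    x = _tone(freq)
    y = bandpass_array(x, SRATE)
    mid = slice(x.shape[1] // 4, 3 * x.shape[1] // 4)
    g = np.sqrt(np.mean(y[0, mid] ** 2) / np.mean(x[0, mid] ** 2))
    return 20 * np.log10(max(g, 1e-12))


class TestBandpass:
    def test_passband_gain_within_1db(self):
        for f in (1.0, 10.0, 25.0):
            assert abs(_gain_db(f)) < 1.0

    def test_stopband_attenuation(self):
        assert _gain_db(50.0) < -30.0
        assert _gain_db(0.05) < -30.0

    def test_dc_offset_removed(self):
        x = np.full((1, int(60 * SRATE)), 5.0)
        y = bandpass_array(x, SRATE)
        mid = slice(x.shape[1] // 4, 3 * x.shape[1] // 4)
        assert np.abs(y[0, mid]).max() < 0.01

    def test_linearity(self, rng):
        x = rng.normal(size=(2, 2000))
        y = rng.normal(size=(2, 2000))
        lhs = bandpass_array(2.0 * x + 3.0 * y, SRATE)
        rhs = 2.0 * bandpass_array(x, SRATE) + 3.0 * bandpass_array(y, SRATE)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_above_nyquist_rejected(self, tiny_cfg):
        es = simulate_epochs(tiny_cfg, ("human", "android"))[0]
        with pytest.raises(ParameterError, match="Nyquist"):
            bandpass(es, 0.5, 80.0)  # srate 125 -> Nyquist 62.5


class TestEpoching:
    def test_event_count_and_window_arithmetic(self, rng):
        cont = rng.normal(size=(4, 5000))
        es, skipped = epoch(
            cont, [(1000, "a"), (2000, "b"), (3000, "a")],
            window=(-200.0, 800.0), srate=1000.0,
            channels=["c1", "c2", "c3", "c4"],
        )
        assert es.data.shape == (3, 4, 1001)
        assert skipped == []
        assert es.times[0] == -200.0 and es.times[-1] == 800.0

    def test_edge_event_reported_and_skipped(self, rng):
        cont = rng.normal(size=(2, 1000))
        es, skipped = epoch(
            cont, [(50, "a"), (500, "b")], window=(-200.0, 300.0),
            srate=1000.0, channels=["c1", "c2"],
        )
        assert es.data.shape[0] == 1
        assert skipped == [(50, "a")]

    def test_concatenated_epochs_recovered_exactly(self, rng):
        srate = 500.0
        n_t = 101
        trials = rng.normal(size=(3, 2, n_t))
        cont = np.concatenate(list(trials), axis=1)
        onsets = [i * n_t + 50 for i in range(3)]  # window -100..+100 ms at 500 Hz
        es, skipped = epoch(
            cont, [(o, "x") for o in onsets], window=(-100.0, 100.0),
            srate=srate, channels=["c1", "c2"],
        )
        assert skipped == []
        assert np.array_equal(es.data, trials)


class TestBaseline:
    def _es(self, data, srate=250.0):
        n_t = data.shape[2]
        times = (np.arange(n_t) - n_t // 2) * (1000.0 / srate)
        return EpochSet(
            data=data, srate=srate, times=times,
            channels=[f"c{i}" for i in range(data.shape[1])],
            conditions=np.array(["x"] * data.shape[0], dtype=object),
            participant="P01",
        )

    def test_constant_trial_becomes_zero(self):
        es = self._es(np.full((1, 2, 100), 5.0))
        out = baseline_correct(es, (-100.0, 0.0))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_baseline_mean_is_zero_and_subtraction_exact(self, rng):
        es = self._es(rng.normal(size=(5, 3, 100)))
        out = baseline_correct(es, (-100.0, 0.0))
        mask = (es.times >= -100.0) & (es.times < 0.0)
        assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-9
        expected = es.data - es.data[:, :, mask].mean(axis=2, keepdims=True)
        assert np.array_equal(out.data, expected)

    def test_idempotent(self, rng):
        es = self._es(rng.normal(size=(4, 2, 100)))
        once = baseline_correct(es)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_empty_window_rejected(self, rng):
        es = self._es(rng.normal(size=(1, 1, 100)))
        with pytest.raises(ParameterError):
            baseline_correct(es, (5000.0, 5001.0))


class TestExclusion:
    def test_planted_noisy_participants_excluded(self, tiny_cfg):
        sets = simulate_epochs(tiny_cfg, ("human", "android"))
        noisy = {1, 3}
        for i in noisy:
            n = sets[i].n_trials
            bad = int(np.ceil(0.3 * n))
            sets[i].data[:bad, 0, 0] = 500.0  # 30% of trials blown out
        kept, excluded = exclude_participants(sets, threshold=100.0, max_bad_fraction=0.2)
        assert {p for p, _ in excluded} == {sets[i].participant for i in noisy}
        assert len(kept) == len(sets) - len(noisy)

    def test_clean_cohort_untouched(self, tiny_cfg):
        sets = simulate_epochs(tiny_cfg, ("human", "android"))
        kept, excluded = exclude_participants(sets)
        assert excluded == []
        assert len(kept) == len(sets)


class TestPooling:
    def _es_const(self, values):
        data = np.tile(np.asarray(values, dtype=float)[None, :, None], (2, 1, 10))
        return EpochSet(
            data=data, srate=1000.0, times=np.arange(10) - 2.0,
            channels=["P6", "P8", "PO6", "PO8"][: len(values)],
            conditions=np.array(["x", "y"], dtype=object),
            participant="P01",
        )

    def test_constant_channels_average(self):
        pt = pool_electrodes(self._es_const([1.0, 2.0, 3.0, 4.0]))
        assert np.allclose(pt.data, 2.5)

    def test_single_channel_identity(self, rng):
        es = self._es_const([1.0, 2.0, 3.0, 4.0])
        es.data = rng.normal(size=es.data.shape)
        pt = pool_electrodes(es, ["P8"])
        assert np.array_equal(pt.data, es.data[:, 1, :])

    def test_matches_bruteforce_loop(self, tiny_cfg):
        es = simulate_epochs(tiny_cfg, ("human", "android"))[0]
        pt = pool_electrodes(es)
        idx = [es.channels.index(e) for e in ("P6", "P8", "PO6", "PO8")]
        for tr in range(es.n_trials):
            for t in range(es.n_times):
                expected = np.mean([es.data[tr, i, t] for i in idx])
                assert pt.data[tr, t] == pytest.approx(expected, abs=1e-12)

    def test_missing_electrode_named(self):
        es = self._es_const([1.0, 2.0])
        with pytest.raises(ParameterError, match="PO8"):
            pool_electrodes(es, ["P6", "PO8"])

    def test_commutes_with_baseline(self, tiny_cfg):
        es = simulate_epochs(tiny_cfg, ("human", "android"))[0]
        a = pool_electrodes(baseline_correct(es)).data
        b = pool_electrodes(es)
        mask = (es.times >= -200.0) & (es.times < 0.0)
        b = b.data - b.data[:, mask].mean(axis=1, keepdims=True)
        assert np.allclose(a, b, atol=1e-10)


class TestGrandMeanCI:
    def test_identical_participants_zero_width(self, rng):
        x = np.tile(rng.normal(size=(1, 50)), (8, 1))
        mean, lo, hi = grand_mean_ci(x, n_boot=500, rng=rng)
        assert np.allclose(lo, hi)
        assert np.allclose(mean, lo)

    def test_band_contains_mean_and_widens_with_spread(self, rng):
        base = rng.normal(size=(1, 30))
        narrow = base + 0.1 * rng.normal(size=(12, 30))
        wide = base + 2.0 * rng.normal(size=(12, 30))
        for x in (narrow, wide):
            mean, lo, hi = grand_mean_ci(x, n_boot=1000, rng=rng)
            assert np.all(lo <= mean + 1e-12) and np.all(mean <= hi + 1e-12)
        _, lo_n, hi_n = grand_mean_ci(narrow, n_boot=1000, rng=rng)
        _, lo_w, hi_w = grand_mean_ci(wide, n_boot=1000, rng=rng)
        assert (hi_w - lo_w).mean() > (hi_n - lo_n).mean()

    def test_coverage_near_nominal(self, rng):
        # Gaussian participant means: the 95% percentile bootstrap CI should
        # cover the true mean at close to nominal rate.
        n_rep, n_sub = 800, 60
        covered = 0
        for _ in range(n_rep):
            x = rng.normal(loc=1.0, size=(n_sub, 1))
            _, lo, hi = bootstrap_mean_ci(x, n_boot=500, rng=rng)
            covered += bool(lo[0] <= 1.0 <= hi[0])
        assert covered / n_rep == pytest.approx(0.95, abs=0.03)

    def test_parameter_validation(self, rng):
        with pytest.raises(ParameterError):
            grand_mean_ci(rng.normal(size=(1, 10)))
        with pytest.raises(ParameterError):
            grand_mean_ci(rng.normal(size=(5, 10)), n_boot=0)
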