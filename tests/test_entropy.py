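"""ApEn/SampEn against the naive enumeration oracle, plus their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrochan import (EntropyParams, SynthConfig, apen, entropy_pair,
                       extract_features, generate_subject, prefilter, sampen)
from entrochan.io import Recording, SegmentAnnotation, epoch_segments

from .oracles import naive_entropies

PARAMS = EntropyParams()


class TestAgainstOracle:
    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 250)
        ap_ref, se_ref = naive_entropies(x)
        assert apen(x) == pytest.approx(ap_ref, abs=1e-12)
        assert sampen(x) == pytest.approx(se_ref, abs=1e-12)

    def test_fixed_seed_uniform(self):
        x = np.random.default_rng(42).uniform(size=100)
        ap_ref, se_ref = naive_entropies(x)
        assert apen(x, EntropyParams(n=100)) == pytest.approx(ap_ref, abs=1e-12)
        assert sampen(x, EntropyParams(n=100)) == pytest.approx(se_ref, abs=1e-12)

    def test_fixed_seed_gaussian(self):
        x = np.random.default_rng(1).standard_normal(200)
        ap_ref, se_ref = naive_entropies(x)
        ap, se = entropy_pair(x, EntropyParams(n=200))
        assert ap == pytest.approx(ap_ref, abs=1e-9)
        assert se == pytest.approx(se_ref, abs=1e-9)

    @pytest.mark.parametrize("n,reps", [(50, 12), (100, 8), (500, 4)])
    def test_random_epochs_match_oracle(self, n, reps):
        """Vectorized entropies equal the O(N^2) enumeration to 1e-9."""
        rng = np.random.default_rng(n)
        for rep in range(reps):
            # mix of signal types: noise, sinusoid+noise, AR-ish smoothness
            kind = rep % 3
            if kind == 0:
                x = rng.standard_normal(n)
            elif kind == 1:
                t = np.arange(n)
                x = np.sin(0.3 * t) + 0.3 * rng.standard_normal(n)
            else:
                x = np.cumsum(rng.standard_normal(n))
            ap_ref, se_ref = naive_entropies(x)
            ap, se = entropy_pair(x, EntropyParams(n=n))
            assert ap == pytest.approx(ap_ref, abs=1e-9)
            assert se == pytest.approx(se_ref, abs=1e-9)

    def test_m3_matches_oracle(self):
        x = np.random.default_rng(9).standard_normal(80)
        ap_ref, se_ref = naive_entropies(x, m=3)
        p = EntropyParams(m=3, n=80)
        assert apen(x, p) == pytest.approx(ap_ref, abs=1e-9)
        assert sampen(x, p) == pytest.approx(se_ref, abs=1e-9)


class TestConventions:
    def test_constant_series_returns_zero(self):
        x = np.full(500, 3.7)
        with pytest.warns(UserWarning, match="degenerate"):
            assert apen(x) == 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            assert sampen(x) == 0.0

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            entropy_pair(np.ones(3), EntropyParams(m=2, n=500))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EntropyParams(m=0)
        with pytest.raises(ValueError):
            EntropyParams(r_coeff=0.0)
        with pytest.raises(ValueError):
            EntropyParams(m=2, n=3)

    def test_sampen_floor_when_no_matches(self):
        # tolerance far below any pairwise distance: zero non-self matches
        x = np.random.default_rng(4).standard_normal(20)
        with pytest.warns(UserWarning, match="floored"):
            se = sampen(x, EntropyParams(r_coeff=1e-9, n=20))
        assert np.isfinite(se)
        # the floor equals one matching ordered pair at each level
        n, m = 20, 2
        expected = np.log(1 / ((n - m) * (n - m + 1))) - np.log(
            1 / ((n - m - 1) * (n - m)))
        assert se == pytest.approx(expected, abs=1e-12)


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), a=st.floats(0.1, 50.0),
           b=st.floats(-100.0, 100.0), neg=st.booleans())
    def test_affine_invariance(self, seed, a, b, neg):
        """x -> a x + b (a != 0) leaves both entropies unchanged (r ~ STD)."""
        x = np.random.default_rng(seed).standard_normal(60)
        scale = -a if neg else a
        ap0, se0 = entropy_pair(x, EntropyParams(n=60))
        ap1, se1 = entropy_pair(scale * x + b, EntropyParams(n=60))
        assert ap1 == pytest.approx(ap0, abs=1e-9)
        assert se1 == pytest.approx(se0, abs=1e-9)

    def test_sampen_nonnegative_when_matches_exist(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.standard_normal(100)
            assert sampen(x, EntropyParams(n=100)) >= 0.0

    def test_monotone_complexity_ordering(self):
        """White noise > sinusoid+noise (SNR 10) > pure sinusoid in mean SampEn."""
        rng = np.random.default_rng(11)
        t = np.arange(500) / 500.0
        sine = np.sin(2 * np.pi * 7 * t)
        means = {}
        for name in ("noise", "mixed", "sine"):
            vals = []
            for _ in range(50):
                if name == "noise":
                    x = rng.standard_normal(500)
                elif name == "mixed":
                    x = sine + np.sqrt(sine.var() / 10) * rng.standard_normal(500)
                else:
                    x = sine + 0.0 * rng.standard_normal(500)  # consume stream
                vals.append(sampen(x))
            means[name] = np.mean(vals)
        assert means["noise"] > means["mixed"] > means["sine"]


class TestExtractFeatures:
    def test_shape_and_labels(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.standard_normal((3, 10 * 500)), 500.0,
                        ("Fp1", "F3", "F7"))
        ann = SegmentAnnotation([(0, 4, "A"), (5, 9, "B")])
        table = extract_features(epoch_segments(rec, ann))
        assert table.values.shape == (10, 6)
        assert list(table.values.columns[:2]) == ["Fp1:ApEn", "Fp1:SampEn"]
        assert list(table.labels) == ["A"] * 5 + ["B"] * 5

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((3, 6 * 500))
        ann = SegmentAnnotation([(0, 5, "A")])
        t1 = extract_features(epoch_segments(
            Recording(data, 500.0, ("Fp1", "F3", "F7")), ann))
        t2 = extract_features(epoch_segments(
            Recording(data[[2, 0, 1]], 500.0, ("F7", "Fp1", "F3")), ann))
        for ch in ("Fp1", "F3", "F7"):
            for kind in ("ApEn", "SampEn"):
                col = f"{ch}:{kind}"
                np.testing.assert_array_equal(t1.values[col], t2.values[col])

    def test_planted_channels_show_larger_label_gap(self, small_synth):
        table = small_synth["table"]
        gt = small_synth["gt"]
        gaps = {}
        for ch in table.channels:
            col = table.values[f"{ch}:SampEn"].to_numpy()
            by = {lab: col[table.labels == lab].mean()
                  for lab in np.unique(table.labels)}
            gaps[ch] = abs(by["calm"] - by["tense"])
        informative = np.mean([gaps[c] for c in gt.informative_channels])
        null = np.mean([g for c, g in gaps.items()
                        if c not in gt.informative_channels])
        assert informative > 3 * null


class TestPrefilter:
    def test_notch_removes_mains(self):
        t = np.arange(20 * 500) / 500.0
        x = np.sin(2 * np.pi * 50 * t)[None, :]
        rec = Recording(x, 500.0, ("Fp1",))
        out = prefilter(rec, notch_hz=50.0, band=None)
        core = out.data[:, 1000:-1000]  # skip filter edge transients
        assert np.sqrt((core ** 2).mean()) < 0.05 * np.sqrt((x ** 2).mean())

    def test_bandpass_removes_dc(self):
        rng = np.random.default_rng(2)
        x = 10.0 + rng.standard_normal((1, 20 * 500))
        rec = Recording(x, 500.0, ("Fp1",))
        out = prefilter(rec, notch_hz=None, band=(0.5, 47.0))
        core = out.data[:, 1000:-1000]
        assert abs(core.mean()) < 0.2

    def test_band_outside_nyquist_rejected(self):
        rec = Recording(np.zeros((1, 1000)), 500.0, ("Fp1",))
        with pytest.raises(ValueError, match="band"):
            prefilter(rec, notch_hz=None, band=(0.5, 300.0))
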