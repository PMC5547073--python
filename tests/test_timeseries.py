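"""Time-series conditioning: nuisance regression, MODWT band-pass, gated
correlation."""

import numpy as np
import pytest
from scipy import stats

from entronet import (
    RoiTimeSeries,
    gated_correlation_matrix,
    modwt,
    modwt_bandpass,
    modwt_detail,
    modwt_passband_hz,
    nuisance_regress,
    read_roi_tsv,
    write_roi_tsv,
)
from entronet.timeseries import read_correlation_tsv, write_correlation_tsv

TR = 1.7
N_VOL = 150


def make_ts(values, tr=TR):
    values = np.atleast_2d(values)
    labels = [f"r{i}" for i in range(values.shape[0])]
    return RoiTimeSeries(values, tr, labels)


def sinusoid(freq_hz, n=N_VOL, tr=TR, phase=0.0):
    t = np.arange(n) * tr
    return np.sin(2 * np.pi * freq_hz * t + phase)


class TestRoiTimeSeries:
    def test_rejects_short_series(self):
        with pytest.raises(ValueError, match="16"):
            make_ts(np.zeros((2, 10)))

    def test_rejects_nan(self):
        vals = np.zeros((2, 30))
        vals[0, 3] = np.nan
        with pytest.raises(ValueError):
            make_ts(vals)

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        ts = make_ts(rng.standard_normal((3, 40)))
        path = tmp_path / "subj_before.tsv"
        write_roi_tsv(ts, path)
        back = read_roi_tsv(path)
        assert back.tr_seconds == ts.tr_seconds
        assert back.region_labels == ts.region_labels
        np.testing.assert_allclose(back.values, ts.values, rtol=1e-9)


class TestNuisanceRegress:
    def test_constant_regressor_centers(self):
        rng = np.random.default_rng(1)
        ts = make_ts(rng.standard_normal((2, 50)))
        out = nuisance_regress(ts, np.zeros((50, 0)))  # intercept only
        np.testing.assert_allclose(
            out.values, ts.values - ts.values.mean(axis=1, keepdims=True), atol=1e-10
        )

    def test_series_equal_to_regressor_vanishes(self):
        reg = sinusoid(0.05, n=60)
        ts = make_ts(3.0 * reg + 1.0)
        out = nuisance_regress(ts, reg[:, None])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_orthogonal_component_survives(self):
        n = 64
        t = np.arange(n)
        reg = np.cos(2 * np.pi * 4 * t / n)  # exact Fourier modes: orthogonal
        keep = np.sin(2 * np.pi * 9 * t / n)
        ts = make_ts(reg + keep)
        out = nuisance_regress(ts, reg[:, None])
        np.testing.assert_allclose(out.values[0], keep, atol=1e-10)

    def test_rank_deficient_names_columns(self):
        x = np.ones((40, 2))
        x[:, 0] = np.arange(40)
        # column 1 duplicates the intercept
        ts = make_ts(np.random.default_rng(2).standard_normal((1, 40)))
        with pytest.raises(ValueError, match=r"\[1\]"):
            nuisance_regress(ts, x)


class TestModwt:
    def test_passband_edges_scale3(self):
        lo, hi = modwt_passband_hz(3, TR)
        assert lo == pytest.approx(1 / (16 * TR))
        assert hi == pytest.approx(1 / (8 * TR))
        assert lo == pytest.approx(0.037, abs=5e-4)
        assert hi == pytest.approx(0.074, abs=5e-4)

    def test_in_band_tone_retained_out_of_band_suppressed(self):
        x_in = sinusoid(0.05)
        x_out = sinusoid(0.25)
        frac_in = (modwt_detail(x_in, 3) ** 2).sum() / (x_in**2).sum()
        frac_out = (modwt_detail(x_out, 3) ** 2).sum() / (x_out**2).sum()
        assert frac_in >= 0.6
        assert frac_out <= 0.1

    def test_constant_series_has_no_detail_energy(self):
        x = np.full(N_VOL, 3.7)
        assert np.abs(modwt_detail(x, 3)).max() == pytest.approx(0.0, abs=1e-10)

    def test_energy_partition(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(128)
        details, smooth = modwt(x, level=4)
        energy = sum((w**2).sum() for w in details) + (smooth**2).sum()
        assert energy == pytest.approx((x**2).sum(), abs=1e-8)

    def test_circular_shift_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(96)
        shift = 17
        d_shifted = modwt_detail(np.roll(x, shift), 3)
        np.testing.assert_allclose(d_shifted, np.roll(modwt_detail(x, 3), shift), atol=1e-10)

    def test_too_short_series_error_states_minimum(self):
        with pytest.raises(ValueError, match="minimum length"):
            modwt(np.zeros(20), level=4)

    def test_bandpass_matrix_matches_rowwise(self):
        rng = np.random.default_rng(5)
        ts = make_ts(rng.standard_normal((4, 80)))
        mat = modwt_bandpass(ts)
        for i in range(4):
            np.testing.assert_allclose(mat[i], modwt_detail(ts.values[i], 3), atol=1e-12)


class TestGatedCorrelation:
    def test_perfect_linear_pair_retained(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(N_VOL)
        cm = gated_correlation_matrix(np.vstack([x, 2 * x]))
        assert cm.r[0, 1] == pytest.approx(1.0)
        assert cm.gate[0, 1]
        assert cm.r[0, 0] == 1.0 and cm.gate[0, 0]

    def test_gate_matches_oracle_formula(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((6, N_VOL))
        cm = gated_correlation_matrix(data, alpha=0.05)
        for i in range(6):
            for j in range(i + 1, 6):
                r, p = stats.pearsonr(data[i], data[j])
                if p < 0.05:
                    assert cm.gate[i, j]
                    assert cm.r[i, j] == pytest.approx(r, abs=1e-10)
                else:
                    assert not cm.gate[i, j]
                    assert cm.r[i, j] == 0.0

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((5, 60))
        cm = gated_correlation_matrix(data)
        np.testing.assert_array_equal(cm.gate, cm.gate.T)
        np.testing.assert_allclose(cm.r, cm.r.T, atol=1e-15)
        perm = rng.permutation(5)
        cm_p = gated_correlation_matrix(data[perm])
        np.testing.assert_allclose(cm_p.r, cm.r[np.ix_(perm, perm)], atol=1e-12)
        np.testing.assert_array_equal(cm_p.gate, cm.gate[np.ix_(perm, perm)])

    def test_zero_variance_region_gated_out_with_warning(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((4, 50))
        data[2] = 5.0
        with pytest.warns(UserWarning, match="zero variance"):
            cm = gated_correlation_matrix(data)
        off = [k for k in range(4) if k != 2]
        assert not cm.gate[2, off].any()
        assert not cm.gate[off, 2].any()
        assert (cm.r[2, off] == 0).all()

    def test_correlation_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        cm = gated_correlation_matrix(rng.standard_normal((5, 70)))
        write_correlation_tsv(cm, tmp_path / "r.tsv", tmp_path / "g.tsv")
        back = read_correlation_tsv(tmp_path / "r.tsv", tmp_path / "g.tsv", n_obs=70)
        np.testing.assert_allclose(back.r, cm.r, atol=1e-9)
        np.testing.assert_array_equal(back.gate, cm.gate)
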