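"""Signal-model tests: closed forms against the numerical Bloch oracle,
timing rules, and the edema-weighting (additive T1+T2) behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edemastir import mr_signal as ms
from edemastir.bloch import simulate_mz_at_readout

INF = math.inf
STIR_REF = ms.SequenceParams("stir", te=100.0, tr=INF, ti=180.0)
REMOTE = ms.TissueParams("remote", 1000.0, 50.0)
EDEMA = ms.TissueParams("edema", 1300.0, 80.0)


class TestValidation:
    @pytest.mark.parametrize("kwargs", [dict(t1=-1, t2=10), dict(t1=100, t2=0), dict(t1=50, t2=80), dict(t1=100, t2=50, pd=0.0), dict(t1=100, t2=50, pd=1.5)])
    def test_bad_tissue_rejected(self, kwargs):
        with pytest.raises(ms.InvalidParameterError):
            ms.TissueParams("bad", **kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="stir", te=100, tr=2000),  # missing ti
            dict(kind="tse", te=100, tr=2000, ti=180),  # ti forbidden
            dict(kind="stir", te=-1, tr=2000, ti=180),
            dict(kind="stir", te=100, tr=250, ti=180),  # tr <= ti + te
            dict(kind="what", te=100, tr=2000),
        ],
    )
    def test_bad_sequence_rejected(self, kwargs):
        with pytest.raises(ms.InvalidParameterError):
            ms.SequenceParams(**kwargs)


class TestStirMagnitude:
    def test_fat_near_null_at_protocol_ti(self):
        # TI 180 ms sits near the zero crossing of a 250 ms T1 species
        fat = ms.TissueParams("fat", 250.0, 80.0)
        sig = ms.stir_magnitude(fat, STIR_REF)
        assert sig.mz_at_readout == pytest.approx(0.02649549, abs=1e-7)
        assert sig.magnitude == pytest.approx(0.00759108, abs=1e-7)

    def test_remote_and_edema_signals(self):
        remote = ms.stir_magnitude(REMOTE, STIR_REF)
        edema = ms.stir_magnitude(EDEMA, STIR_REF)
        # both still inverted at the excitation pulse
        assert remote.mz_at_readout == pytest.approx(-0.67054042, abs=1e-7)
        assert edema.mz_at_readout == pytest.approx(-0.74139348, abs=1e-7)
        assert remote.magnitude == pytest.approx(0.09074778, abs=1e-7)
        assert edema.magnitude == pytest.approx(0.21241279, abs=1e-7)
        assert edema.magnitude > remote.magnitude  # edema hyperintense

    def test_immediate_readout_after_inversion(self):
        seq = ms.SequenceParams("stir", te=50.0, tr=INF, ti=1e-9)
        tissue = ms.TissueParams("x", 800.0, 60.0, pd=0.7)
        sig = ms.stir_magnitude(tissue, seq)
        assert sig.mz_at_readout == pytest.approx(-1.0, abs=1e-9)
        assert sig.magnitude == pytest.approx(0.7 * math.exp(-50.0 / 60.0), rel=1e-9)


class TestTseMagnitude:
    def test_full_relaxation(self):
        seq = ms.SequenceParams("tse", te=100.0, tr=INF)
        sig = ms.tse_magnitude(REMOTE, seq)
        assert sig.mz_at_readout == 1.0
        assert sig.magnitude == pytest.approx(math.exp(-2.0), rel=1e-12)

    def test_linear_in_proton_density(self):
        seq = ms.SequenceParams("tse", te=80.0, tr=1500.0)
        half = ms.TissueParams("h", 900.0, 70.0, pd=0.5)
        full = ms.TissueParams("f", 900.0, 70.0, pd=1.0)
        assert ms.tse_magnitude(full, seq).magnitude == pytest.approx(
            2 * ms.tse_magnitude(half, seq).magnitude, rel=1e-12
        )

    def test_t1_opposes_t2_in_plain_tse(self):
        # longer T1 alone lowers the saturation-recovery signal
        seq = ms.SequenceParams("tse", te=100.0, tr=2000.0)
        t1s = np.linspace(600, 1600, 11)
        mags = [ms.tse_magnitude(ms.TissueParams("t", t1, 50.0), seq).magnitude for t1 in t1s]
        assert np.all(np.diff(mags) < 0)


class TestIrGre:
    def test_nulled_tissue_is_dark(self):
        seq = ms.SequenceParams("ir_gre", te=2.0, tr=1e9, ti=450.0 * math.log(2))
        nulled = ms.TissueParams("myo", 450.0, 45.0)
        assert ms.ir_gre_magnitude(nulled, seq).magnitude == pytest.approx(0.0, abs=1e-9)

    def test_scar_bright_against_nulled_remote(self):
        ti = ms.null_ti(600.0, 2000.0)
        seq = ms.SequenceParams("ir_gre", te=2.0, tr=2000.0, ti=ti)
        remote = ms.TissueParams("remote_post", 600.0, 50.0)
        scar = ms.TissueParams("scar_post", 400.0, 50.0)
        assert ms.ir_gre_magnitude(remote, seq).magnitude == pytest.approx(0.0, abs=1e-12)
        assert ms.ir_gre_magnitude(scar, seq).magnitude > 0.1


class TestNullTi:
    def test_fat_null_near_protocol_ti(self):
        assert ms.null_ti(250.0) == pytest.approx(250.0 * math.log(2), rel=1e-15)
        assert ms.null_ti(250.0) == pytest.approx(173.2868, abs=1e-3)

    @given(st.floats(min_value=50.0, max_value=3000.0))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariance_long_tr(self, t1):
        assert ms.null_ti(t1) / t1 == pytest.approx(math.log(2), rel=1e-12)

    def test_finite_tr_shortens_null_time(self):
        assert ms.null_ti(1000.0, 4000.0) < 1000.0 * math.log(2)

    def test_matches_root_finder(self):
        from scipy.optimize import brentq

        for t1, tr in [(250.0, INF), (1000.0, 4000.0), (600.0, 2000.0)]:
            f = lambda ti: 1 - 2 * math.exp(-ti / t1) + (0 if math.isinf(tr) else math.exp(-tr / t1))
            root = brentq(f, 1e-6, t1 * 2)
            assert ms.null_ti(t1, tr) == pytest.approx(root, rel=1e-10)

    def test_nulling_suppresses_stir_signal(self):
        for t1 in (200.0, 250.0, 400.0, 1000.0):
            seq = ms.SequenceParams("stir", te=60.0, tr=INF, ti=ms.null_ti(t1))
            mag = ms.stir_magnitude(ms.TissueParams("t", t1, 50.0), seq).magnitude
            assert mag <= 1e-12


class TestTrFromHeartRate:
    @pytest.mark.parametrize("hr,expected", [(60, 2000.0), (80, 1500.0), (90, 8000.0 / 3)])
    def test_gating_rule(self, hr, expected):
        assert ms.tr_from_heart_rate(hr) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("hr", [10, 300, 0])
    def test_out_of_range(self, hr):
        with pytest.raises(ms.InvalidParameterError):
            ms.tr_from_heart_rate(hr)


class TestRelaxationCurves:
    def test_endpoints_match_signal_model(self):
        seq = ms.SequenceParams("stir", te=100.0, tr=2000.0, ti=180.0)
        curves = ms.relaxation_curves(ms.REFERENCE_TISSUES, seq, n_points=50)
        for tissue in ms.REFERENCE_TISSUES:
            sig = ms.stir_magnitude(tissue, seq)
            c = curves[tissue.name]
            assert c.mz[-1] == pytest.approx(sig.mz_at_readout, rel=1e-12)
            assert c.mxy[-1] == pytest.approx(sig.magnitude, rel=1e-12)
            # continuity at the excitation pulse
            assert c.mxy[0] == pytest.approx(tissue.pd * abs(sig.mz_at_readout), rel=1e-12)

    def test_initial_mz_reflects_finite_tr(self):
        seq = ms.SequenceParams("stir", te=100.0, tr=1500.0, ti=150.0)
        curves = ms.relaxation_curves(ms.REFERENCE_TISSUES, seq)
        for tissue in ms.REFERENCE_TISSUES:
            assert curves[tissue.name].mz[0] == pytest.approx(
                -1.0 + math.exp(-1500.0 / tissue.t1), rel=1e-12
            )

    def test_readout_ordering_of_reference_tissues(self):
        # magnitude order at readout: edema > remote > B > fat > A
        # (A's TE/T2 = 5 pushes it below the near-nulled fat signal)
        curves = ms.relaxation_curves(ms.REFERENCE_TISSUES, STIR_REF)
        finals = {name: c.mxy[-1] for name, c in curves.items()}
        assert finals["edema"] > finals["remote"] > finals["B"] > finals["fat"] > finals["A"]


class TestContrast:
    def test_reference_pair_value(self):
        assert ms.contrast(EDEMA, REMOTE, STIR_REF) == pytest.approx(0.12166501, abs=1e-7)

    def test_antisymmetric_and_zero_on_identical(self):
        seq = ms.SequenceParams("stir", te=100.0, tr=2000.0, ti=180.0)
        assert ms.contrast(EDEMA, REMOTE, seq) == pytest.approx(-ms.contrast(REMOTE, EDEMA, seq))
        assert ms.contrast(REMOTE, REMOTE, seq) == 0.0

    def test_inversion_boosts_relative_edema_contrast(self):
        # edema conspicuity against remote: STIR beats the same readout
        # without inversion, at matched TE/TR
        for tr in (2000.0, 1500.0, INF):
            stir = ms.SequenceParams("stir", te=100.0, tr=tr, ti=180.0)
            tse = ms.SequenceParams("tse", te=100.0, tr=tr)
            assert ms.relative_contrast(EDEMA, REMOTE, stir) > ms.relative_contrast(
                EDEMA, REMOTE, tse
            )

    def test_contrast_positive_and_continuous_over_te(self):
        # edema-remote contrast persists over the long-TE plateau
        tes = np.linspace(50.0, 120.0, 36)
        values = [
            ms.contrast(EDEMA, REMOTE, ms.SequenceParams("stir", te=te, tr=INF, ti=180.0))
            for te in tes
        ]
        assert all(v > 0 for v in values)
        assert np.max(np.abs(np.diff(values))) < 0.01  # no jumps
        # plateau: doubling TE from 50 to 100 changes contrast by a bounded factor
        assert 0.5 < values[-11] / values[0] < 2.0  # te 100 vs te 50


class TestMonotonicity:
    def test_stir_increases_with_t1_while_inverted(self):
        # with long TR and Mz(TI) < 0, longer T1 means larger magnitude
        t1s = np.linspace(600.0, 1600.0, 21)
        mags = [
            ms.stir_magnitude(ms.TissueParams("t", t1, 50.0), STIR_REF).magnitude for t1 in t1s
        ]
        mzs = [ms.inversion_recovery_mz(t1, 180.0, INF) for t1 in t1s]
        assert all(m < 0 for m in mzs)
        assert np.all(np.diff(mags) > 0)


class TestBlochOracle:
    @pytest.mark.parametrize("tr", [1000.0, 2000.0, INF])
    def test_closed_form_matches_numerical_integration(self, tr):
        for t1 in (100.0, 400.0, 700.0, 1000.0, 1300.0, 1600.0):
            for ti in (100.0, 180.0, 300.0):
                closed = ms.inversion_recovery_mz(t1, ti, tr)
                simulated = simulate_mz_at_readout(t1, ti, tr)
                assert abs(closed - simulated) <= 1e-9


class TestMagnitudeMap:
    def test_matches_scalar_model(self):
        seq = ms.SequenceParams("stir", te=100.0, tr=2000.0, ti=180.0)
        t1 = np.array([[1000.0, 1300.0]])
        t2 = np.array([[50.0, 80.0]])
        pd = np.array([[1.0, 1.0]])
        out = ms.magnitude_map(t1, t2, pd, seq)
        assert out[0, 0] == pytest.approx(ms.stir_magnitude(REMOTE, seq).magnitude, rel=1e-12)
        assert out[0, 1] == pytest.approx(ms.stir_magnitude(EDEMA, seq).magnitude, rel=1e-12)

    def test_zero_pd_yields_zero(self):
        seq = ms.SequenceParams("ir_gre", te=2.0, tr=2000.0, ti=400.0)
        out = ms.magnitude_map(np.full((2, 2), 500.0), np.full((2, 2), 50.0), np.zeros((2, 2)), seq)
        assert np.all(out == 0)
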