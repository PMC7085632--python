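import warnings

import numpy as np
import pytest

from deltaz import (
    ConfigurationError,
    DCResidualWarning,
    DomainError,
    ExcitationSpec,
    QuadratureSamples,
    SamplerConfig,
    demod_dc,
    demod_differential,
    demod_quadrature,
    demod_three_sample,
    demod_two_sample,
    make_impedance_trace,
    restore_from_differences,
    rev_approx_error,
    rev_only_modulus,
    sample_quadrature,
    synthesize_response,
)
from conftest import ramp_response


def make_samples(s_rows, f=1e3, stride=1):
    """Hand-built QuadratureSamples from explicit (s1,s2,s3,s4) rows."""
    s = np.atleast_2d(np.asarray(s_rows, dtype=float))
    n = s.shape[0]
    T = 1.0 / f
    t = (np.arange(n) * stride)[:, None] * T + np.array([0, 0.25, 0.5, 0.75]) * T
    return QuadratureSamples(
        period_index=np.arange(n) * stride, t=t, s=s, frequency=f, stride=stride
    )


class TestDemodDC:
    def test_offset_recovery(self):
        """Unit sinusoid plus 0.5 offset: DC = 0.5 from both phase pairs."""
        phi = 0.0
        row = [0.5 + 0, 0.5 + 1, 0.5 - 0, 0.5 - 1]
        dc = demod_dc(make_samples([row] * 3))
        np.testing.assert_allclose(dc.dc13, 0.5)
        np.testing.assert_allclose(dc.dc24, 0.5)
        np.testing.assert_allclose(dc.discrepancy, 0.0)

    def test_zero_mean_gives_zero(self):
        dc = demod_dc(make_samples([[0.1, 0.9, -0.1, -0.9]]))
        np.testing.assert_allclose(dc.dc, 0.0, atol=1e-15)

    def test_ramp_envelope_discrepancy_matches_dense_oracle(self):
        """On a ramped envelope the two DC estimates differ; the discrepancy
        equals the value computed by dense simulation."""
        a, f = 0.1, 1e3
        resp, exc = ramp_response(a, f=f)
        qs = sample_quadrature(resp, exc)
        dc = demod_dc(qs)
        # dense oracle: at phi=0 the 0/180-deg samples vanish (dc13 = 0) while
        # dc24 reads the envelope difference between the 90- and 270-deg instants
        T = 1.0 / f
        t0 = qs.t[:, 0]
        oracle_dc24 = 0.5 * ((1 + a * (t0 + T / 4)) - (1 + a * (t0 + 3 * T / 4)))
        np.testing.assert_allclose(dc.dc13, 0.0, atol=1e-12)
        np.testing.assert_allclose(dc.discrepancy, -oracle_dc24, atol=1e-12)

    def test_insufficient_phases_rejected(self, unit_response, exc_1khz):
        qs = sample_quadrature(
            unit_response, exc_1khz, SamplerConfig(phase_set=(0, 90))
        )
        with pytest.raises(ConfigurationError):
            demod_dc(qs)


class TestDemodQuadrature:
    @pytest.mark.parametrize(
        "row, modulus, phase",
        [
            ([0, 1, 0, -1], 1.0, 0.0),
            (
                [
                    np.sin(np.deg2rad(4.3)),  # 0.074979
                    np.cos(np.deg2rad(4.3)),  # 0.997185
                    -np.sin(np.deg2rad(4.3)),
                    -np.cos(np.deg2rad(4.3)),
                ],
                1.0,
                4.3,
            ),
            ([3, 4, -3, -4], 5.0, np.degrees(np.arctan2(3, 4))),
        ],
    )
    def test_modulus_and_phase(self, row, modulus, phase):
        r = demod_quadrature(make_samples([row]))
        assert r.modulus[0] == pytest.approx(modulus, abs=5e-6)
        assert r.phase_deg[0] == pytest.approx(phase, abs=5e-4)

    def test_three_four_five_angle(self):
        r = demod_quadrature(make_samples([[3, 4, -3, -4]]))
        assert r.phase_deg[0] == pytest.approx(36.870, abs=1e-3)  # atan(3/4)

    def test_end_to_end_recovery_is_exact(self):
        """Noiseless constant envelope: configured (M, phi) recovered to 1e-9."""
        time = np.array([0.0, 0.01])
        imp = make_impedance_trace(70.39, 4.3, np.zeros(2), time)
        exc = ExcitationSpec(frequency=1e3, amplitude=1.0)
        resp = synthesize_response(imp, exc, oversample=64)
        r = demod_quadrature(sample_quadrature(resp, exc))
        np.testing.assert_allclose(r.modulus, 70.39, rtol=1e-9)
        np.testing.assert_allclose(r.phase_deg, 4.3, rtol=1e-9)

    def test_offset_invariance_of_rev_imv(self):
        base = np.array([0.1, 0.9, -0.1, -0.9])
        r0 = demod_quadrature(make_samples([base]))
        r1 = demod_quadrature(make_samples([base + 0.37]))
        assert r1.ReV[0] == pytest.approx(r0.ReV[0], abs=1e-14)
        assert r1.ImV[0] == pytest.approx(r0.ImV[0], abs=1e-14)

    def test_modulus_identity(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(50, 4))
        r = demod_quadrature(make_samples(rows))
        np.testing.assert_allclose(r.modulus ** 2, r.ReV ** 2 + r.ImV ** 2, rtol=1e-12)

    def test_missing_phase_rejected(self, unit_response, exc_1khz):
        qs = sample_quadrature(
            unit_response, exc_1khz, SamplerConfig(phase_set=(0, 90, 180))
        )
        with pytest.raises(ConfigurationError):
            demod_quadrature(qs)


class TestDemodThreeSample:
    def test_matches_four_sample_for_constant_envelope(self):
        import numpy as _np
        sp, cp = _np.sin(_np.deg2rad(4.3)), _np.cos(_np.deg2rad(4.3))
        rows = [[sp, cp, -sp, -cp]] * 4
        r4 = demod_quadrature(make_samples(rows))
        r3 = demod_three_sample(make_samples(rows))
        np.testing.assert_allclose(r3.modulus, r4.modulus, atol=1e-14)
        np.testing.assert_allclose(r3.phase_deg, r4.phase_deg, atol=1e-12)

    def test_dc_contaminated_input_recovers_clean_result(self):
        """A 0.5 V offset is absorbed by the DC estimate: same modulus/phase
        as the uncontaminated four-sample result."""
        sp, cp = np.sin(np.deg2rad(4.3)), np.cos(np.deg2rad(4.3))
        clean = np.array([sp, cp, -sp, -cp])
        r4 = demod_quadrature(make_samples([clean]))
        r3 = demod_three_sample(make_samples([clean + 0.5]))
        assert r3.modulus[0] == pytest.approx(r4.modulus[0], abs=1e-12)
        assert r3.phase_deg[0] == pytest.approx(r4.phase_deg[0], abs=1e-10)

    def test_270_variant_sign_corrected(self):
        sp, cp = np.sin(np.deg2rad(4.3)), np.cos(np.deg2rad(4.3))
        rows = [[sp, cp, -sp, -cp]]
        r90 = demod_three_sample(make_samples(rows), quadrature_phase=90)
        r270 = demod_three_sample(make_samples(rows), quadrature_phase=270)
        assert r270.ImV[0] == pytest.approx(r90.ImV[0], abs=1e-14)


class TestDemodDifferential:
    def test_constant_envelope_gives_zero(self):
        rows = [[0.0, 1.0, 0.0, -1.0]] * 5
        d = demod_differential(make_samples(rows))
        np.testing.assert_allclose(d.dReV, 0.0, atol=1e-15)
        np.testing.assert_allclose(d.dImV, 0.0, atol=1e-15)

    def test_ramp_envelope_matches_dense_oracle(self):
        """Envelope 1 + a*t at a = 0.1/s, 1 kHz: the in-phase difference per
        period is -a*T/4 (dense-simulation value, exact for a linear ramp)."""
        a, f = 0.1, 1e3
        resp, exc = ramp_response(a, f=f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DCResidualWarning)
            d = demod_differential(sample_quadrature(resp, exc))
        np.testing.assert_allclose(d.dReV, -a / f / 4.0, rtol=1e-9)

    def test_negated_ramp_negates_output(self):
        a, f = 0.05, 1e3
        rp, exc = ramp_response(a, f=f, Z0=2.0)
        rm, _ = ramp_response(-a, f=f, Z0=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DCResidualWarning)
            dp = demod_differential(sample_quadrature(rp, exc))
            dm = demod_differential(sample_quadrature(rm, exc))
        np.testing.assert_allclose(dp.dReV, -dm.dReV, atol=1e-15)


class TestDemodTwoSample:
    def test_constant_envelope_raw_channels(self):
        """Zero-DC constant envelope: raw s1 = M sin(phi), s2 = M cos(phi)."""
        phi = np.deg2rad(4.3)
        rows = [[np.sin(phi), np.cos(phi), np.nan, np.nan]] * 4
        s = make_samples(rows)
        d = demod_two_sample(s)
        np.testing.assert_allclose(d.raw_0deg, np.sin(phi))
        np.testing.assert_allclose(d.raw_90deg, np.cos(phi))
        np.testing.assert_allclose(d.dReV, 0.0, atol=1e-15)

    def test_matches_differential_for_slow_envelope(self):
        """Slowly varying triangle envelope: the two-sample (consecutive
        record) differences equal the half-period differences exactly on the
        linear flanks; only the few records straddling a triangle corner
        deviate."""
        f = 1e5
        t_env = np.linspace(0.0, 0.05, 5001)
        tri = 1e-3 * np.abs(2 * (t_env * 10 % 1) - 1)  # 10 Hz triangle
        imp = make_impedance_trace(1.0, 0.0, tri, t_env)
        exc = ExcitationSpec(frequency=f)
        resp = synthesize_response(imp, exc, oversample=16)
        qs = sample_quadrature(resp, exc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DCResidualWarning)
            d6 = demod_differential(qs)
        d7 = demod_two_sample(qs)
        scale = np.max(np.abs(d6.dReV))
        err = np.abs(d7.dReV - d6.dReV[1:]) / scale
        assert np.median(err) < 1e-6
        assert np.mean(err > 1e-6) < 1e-3  # only corner-straddling records

    def test_zero_phase_kills_raw_s1(self, unit_response, exc_1khz):
        d = demod_two_sample(sample_quadrature(unit_response, exc_1khz))
        np.testing.assert_allclose(d.raw_0deg, 0.0, atol=1e-12)


class TestRevOnly:
    def test_no_phase_is_identity(self):
        x = np.array([0.1, 0.5])
        np.testing.assert_array_equal(rev_only_modulus(x), x)

    def test_correction_at_4p3_deg(self):
        assert rev_only_modulus(0.99718, 4.3) == pytest.approx(1.0, abs=1e-5)

    def test_correction_factor_at_45deg(self):
        assert rev_only_modulus(1.0, 45.0) == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_out_of_domain_rejected(self):
        with pytest.raises(DomainError):
            rev_only_modulus(1.0, 90.0)


class TestRevApproxError:
    def test_zero_phase_zero_error(self):
        assert rev_approx_error(0.0) == 0.0

    def test_four_degrees_is_0p24_percent(self):
        """The single-channel modulus error at 4 deg is approximately 0.24 %."""
        assert round(rev_approx_error(4.0) * 100, 2) == 0.24

    def test_45_degrees(self):
        assert rev_approx_error(45.0) == pytest.approx(np.sqrt(2) - 1, rel=1e-12)

    def test_equals_inverse_cosine_form(self):
        phi = np.linspace(-80, 80, 161)
        lhs = rev_approx_error(phi)
        rhs = np.sqrt(1 + np.tan(np.deg2rad(phi)) ** 2) - 1
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_domain_edge_rejected(self):
        with pytest.raises(DomainError):
            rev_approx_error(90.0)


class TestRestoreFromDifferences:
    def test_zero_differences_zero_restoration(self):
        rows = [[0.0, 1.0, 0.0, -1.0]] * 10
        d = demod_differential(make_samples(rows))
        restored = restore_from_differences(d)
        np.testing.assert_array_equal(restored, 0.0)

    def test_ramp_differences_restore_linear_growth(self):
        """Pure ramp envelope: restored output is the (leak-biased) linear
        envelope change; with a long time constant the analytic a*t line is
        matched closely."""
        a, f, dur = 0.2, 1e3, 1.0
        resp, exc = ramp_response(a, f=f, duration=dur, Z0=5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DCResidualWarning)
            d = demod_differential(sample_quadrature(resp, exc))
        restored = restore_from_differences(d, leak_tc=np.inf)
        t = (d.period_index + 1) / f
        np.testing.assert_allclose(restored, a * t, rtol=1e-6)
        # leaky version is biased low but within the leak bound a*tc*(1-exp)
        restored_leaky = restore_from_differences(d, leak_tc=10.0)
        bias = a * t - restored_leaky
        assert np.all(bias >= -1e-9)
        assert np.max(bias) <= a * dur ** 2 / (2 * 10.0) * 1.05
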