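"""Unit and property tests for the compressibility derivation chain."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liposonics import (
    InstrumentPrecision,
    MediumPoint,
    PairedScan,
    SuspensionPoint,
    apparent_specific_volume,
    bulk_modulus,
    compressibility,
    derive_scan,
    generate_scans,
    lipid_compressibility,
    specific_compressibility,
    velocity_increment,
)
from liposonics.acoustics import NonPhysicalCompressibilityWarning


class TestSingleValueOperations:
    @pytest.mark.parametrize(
        "u, rho, expected",
        [
            (1.0, 1e-3, 1.0),                      # unit identity: 1 m/s, 1 kg/m3
            (1497.0, 0.9970, 4.4757e-10),          # water-like regime
        ],
    )
    def test_compressibility_values(self, u, rho, expected):
        assert compressibility(u, rho) == pytest.approx(expected, rel=1e-4)

    def test_compressibility_quarter_on_doubled_velocity(self):
        assert compressibility(2 * 1500.0, 1.0) == pytest.approx(
            compressibility(1500.0, 1.0) / 4.0, rel=1e-14)

    @pytest.mark.parametrize("u,rho", [(0, 1), (1, 0), (-1, 1), (1, -1)])
    def test_compressibility_domain(self, u, rho):
        with pytest.raises(ValueError):
            compressibility(u, rho)

    def test_velocity_increment_values(self):
        assert velocity_increment(1500.0, 1500.0, 2.0) == 0.0
        # 0.30 / (1500 * 0.002 g/mL)
        assert velocity_increment(1500.30, 1500.00, 2.0) == pytest.approx(0.100, rel=1e-10)

    def test_velocity_increment_sign_flip(self):
        a = velocity_increment(1500.30, 1500.00, 2.0)
        b = velocity_increment(1500.00, 1500.30, 2.0)
        assert b < 0 < a
        assert b == pytest.approx(-a, rel=1e-3)  # first order in (u - u0)

    def test_velocity_increment_requires_positive_concentration(self):
        with pytest.raises(ValueError):
            velocity_increment(1500.0, 1499.0, 0.0)

    def test_apparent_specific_volume_values(self):
        # solvent-density solute contributes exactly 1/rho0
        assert apparent_specific_volume(0.997, 0.997, 2.0) == pytest.approx(1 / 0.997)
        assert apparent_specific_volume(0.99706, 0.99700, 2.0) == pytest.approx(
            (1 - 0.03) / 0.997, rel=1e-12)

    def test_apparent_specific_volume_monotone_decreasing_in_rho(self):
        lighter = apparent_specific_volume(0.99690, 0.99700, 2.0)
        assert lighter > 1 / 0.99700

    def test_specific_compressibility_values(self):
        assert specific_compressibility(0.0, 1 / 0.997, 0.997) == pytest.approx(1 / 0.997)
        assert specific_compressibility(0.1, 0.97, 0.997) == pytest.approx(
            -0.2 - 1 / 0.997 + 1.94, rel=1e-12)

    def test_specific_compressibility_affine_slopes(self):
        base = specific_compressibility(0.1, 0.97, 0.997)
        assert specific_compressibility(0.1 + 1.0, 0.97, 0.997) - base == pytest.approx(-2.0)
        assert specific_compressibility(0.1, 0.97 + 1.0, 0.997) - base == pytest.approx(2.0)

    def test_lipid_compressibility_values(self):
        assert lipid_compressibility(4.4e-10, 0.0, 0.97) == pytest.approx(8.8e-10)
        assert lipid_compressibility(4.4e-10, 0.1, 0.97) == pytest.approx(
            4.4e-10 * (2 - 0.1 / 0.97), rel=1e-12)

    def test_lipid_compressibility_monotone_decreasing_in_increment(self):
        lo = lipid_compressibility(4.4e-10, 0.2, 0.97)
        hi = lipid_compressibility(4.4e-10, 0.1, 0.97)
        assert lo < hi

    def test_lipid_compressibility_nonphysical_warns_not_raises(self):
        with pytest.warns(NonPhysicalCompressibilityWarning):
            out = lipid_compressibility(4.4e-10, 2.5, 1.0)
        assert out < 0

    def test_bulk_modulus_reciprocal(self):
        assert bulk_modulus(1.0) == 1.0
        assert bulk_modulus(8.346e-10) == pytest.approx(1.198e9, rel=1e-3)
        beta = lipid_compressibility(4.4e-10, 0.1, 0.97)
        assert bulk_modulus(beta) * beta == pytest.approx(1.0, abs=1e-15)

    def test_bulk_modulus_domain(self):
        with pytest.raises(ValueError):
            bulk_modulus(-1e-10)


@settings(max_examples=200, derandomize=True)
@given(
    u=st.floats(1200, 1800),
    u0=st.floats(1200, 1800),
    rho=st.floats(0.9, 1.1),
    rho0=st.floats(0.9, 1.1),
    c=st.floats(0.5, 10.0),
)
def test_oracle_equivalence_extended_precision(u, u0, rho, rho0, c):
    """Each operation matches a longdouble transliteration of its formula."""
    ul, u0l, rl, r0l, cl = (np.longdouble(x) for x in (u, u0, rho, rho0, c))
    cpl = cl * np.longdouble(1e-3)
    assert compressibility(u, rho) == pytest.approx(
        float(1 / (ul**2 * rl * np.longdouble(1000))), rel=1e-12)
    assert velocity_increment(u, u0, c) == pytest.approx(
        float((ul - u0l) / (u0l * cpl)), rel=1e-9, abs=1e-12)
    assert apparent_specific_volume(rho, rho0, c) == pytest.approx(
        float((1 - (rl - r0l) / cpl) / r0l), rel=1e-9, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(st.floats(0.9, 1.1), st.floats(1200, 1800))
def test_unit_coherence_si_inputs(rho_gcc, u):
    """Pre-converting the density to SI and using the raw formula agrees to 1e-12."""
    direct = compressibility(u, rho_gcc)
    si = 1.0 / (u**2 * (rho_gcc * 1000.0))
    assert direct == pytest.approx(si, rel=1e-12)


class TestDeriveScan:
    def test_single_point_scan_matches_scalar_operations(self):
        solv = [MediumPoint(25.0, 0.99700, 1497.00)]
        susp = [SuspensionPoint(25.0, 0.99706, 1497.30, 2.0)]
        d = derive_scan(PairedScan(solv, susp))
        row = d.table.iloc[0]
        assert row["beta0_Pa"] == pytest.approx(compressibility(1497.00, 0.99700))
        assert row["beta_s_Pa"] == pytest.approx(compressibility(1497.30, 0.99706))
        assert row["u_increment_mL_per_g"] == pytest.approx(
            velocity_increment(1497.30, 1497.00, 2.0))
        assert row["phi_v_mL_per_g"] == pytest.approx(
            apparent_specific_volume(0.99706, 0.99700, 2.0))

    def test_noise_free_round_trip_recovers_ground_truth(self, noiseless_config):
        scan, truth = generate_scans(noiseless_config)
        table = derive_scan(scan, noiseless_config.precision).table
        for col, tv in [
            ("u_increment_mL_per_g", truth.u_increment),
            ("phi_v_mL_per_g", truth.phi_v),
            ("phi_k_over_beta0_mL_per_g", truth.phi_k_over_beta0),
            ("K_lipid_Pa", truth.K_lipid),
        ]:
            np.testing.assert_allclose(table[col].to_numpy(), tv, rtol=1e-10)

    def test_reciprocal_invariant_every_row(self, default_config):
        scan, _ = generate_scans(default_config)
        t = derive_scan(scan).table
        ok = ~t["nonphysical"]
        np.testing.assert_allclose(
            (t["K_lipid_Pa"] * t["beta_lipid_Pa"])[ok], 1.0, rtol=1e-14)

    def test_uncertainties_scale_linearly_with_precision(self, default_config):
        scan, _ = generate_scans(default_config)
        p1 = InstrumentPrecision(1e-5, 0.01, 0.01)
        p2 = InstrumentPrecision(2e-5, 0.02, 0.02)
        s1 = derive_scan(scan, p1).table
        s2 = derive_scan(scan, p2).table
        for col in s1.columns:
            if col.startswith("sigma_"):
                np.testing.assert_allclose(
                    s2[col].to_numpy(), 2.0 * s1[col].to_numpy(), rtol=1e-5)

    def test_unpairable_temperatures_error_lists_rows(self):
        solv = [MediumPoint(20.0 + i, 0.998, 1480.0 + i) for i in range(5)]
        susp = [SuspensionPoint(30.0, 0.998, 1481.0, 2.0)]
        with pytest.raises(ValueError, match="T=30"):
            derive_scan(PairedScan(solv, susp))

    def test_interpolates_solvent_between_nodes(self):
        solv = [MediumPoint(20.0, 0.9980, 1480.0), MediumPoint(22.0, 0.9978, 1486.0)]
        susp = [SuspensionPoint(21.0, 0.9979 + 2e-5, 1483.2, 2.0)]
        row = derive_scan(PairedScan(solv, susp)).table.iloc[0]
        assert row["u_increment_mL_per_g"] == pytest.approx(
            velocity_increment(1483.2, 1483.0, 2.0))

    def test_metadata_records_parse_and_conversions(self, default_config):
        scan, _ = generate_scans(default_config)
        meta = derive_scan(scan).metadata
        assert meta["eq5_parse"] == "two_minus_u_over_phiv"
        assert "density" in meta["unit_conversions"]
        assert meta["temperature_tolerance_C"] == 0.05

    def test_alternative_parse_changes_lipid_compressibility_only(self, noiseless_config):
        scan, _ = generate_scans(noiseless_config)
        a = derive_scan(scan, noiseless_config.precision, parse="two_minus_u_over_phiv").table
        b = derive_scan(scan, noiseless_config.precision, parse="phik_over_phiv").table
        np.testing.assert_allclose(
            a["phi_k_over_beta0_mL_per_g"], b["phi_k_over_beta0_mL_per_g"], rtol=1e-14)
        assert not np.allclose(a["beta_lipid_Pa"], b["beta_lipid_Pa"], rtol=1e-3, atol=0)


class TestDomainTypes:
    def test_medium_point_invariants(self):
        with pytest.raises(ValueError):
            MediumPoint(150.0, 0.997, 1500.0)
        with pytest.raises(ValueError):
            MediumPoint(25.0, -1.0, 1500.0)

    def test_suspension_point_needs_positive_concentration(self):
        with pytest.raises(ValueError):
            SuspensionPoint(25.0, 0.997, 1500.0, 0.0)

    def test_paired_scan_rejects_non_monotone_temperatures(self):
        pts = [MediumPoint(t, 0.997, 1500.0) for t in (20.0, 22.0, 21.0)]
        susp = [SuspensionPoint(21.0, 0.998, 1501.0, 2.0)]
        with pytest.raises(ValueError, match="monotone"):
            PairedScan(pts, susp)

    def test_paired_scan_accepts_decreasing_scan_direction(self):
        pts = [MediumPoint(t, 0.997, 1500.0) for t in (25.0, 24.0, 23.0)]
        susp = [SuspensionPoint(24.0, 0.998, 1501.0, 2.0)]
        derive_scan(PairedScan(pts, susp))  # must not raise
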