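"""Fluorescence yield algebra, the unit constant, and the two ETR variants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phiec.frrf import (
    CHLA_MOLAR_MASS_MG,
    FRRfAcquisition,
    InvalidAcquisitionError,
    NPsiiMode,
    NPsiiSpec,
    SpectralCorrection,
    correct_sigma,
    derive_yields,
    etr_dark_reference,
    etr_light_dark,
    resolve_npsii,
    unit_conversion_factor,
)
from conftest import random_acquisition


class TestDeriveYields:
    def test_hand_arithmetic(self):
        acq = FRRfAcquisition(F0=0.30, Fm=1.00, F0p=0.28, Fp=0.60, Fmp=0.90,
                              sigma_psii=400, E=100)
        y = derive_yields(acq)
        assert y.FvFm == pytest.approx(0.700, abs=1e-12)
        assert y.FqpFmp == pytest.approx(0.333333, abs=1e-6)
        assert y.FqpFvp == pytest.approx(0.483871, abs=1e-6)

    def test_reference_optimum_fvfm(self):
        y = derive_yields(FRRfAcquisition(F0=0.35, Fm=1.0, sigma_psii=400, E=0))
        assert y.FvFm == pytest.approx(0.65)

    def test_fully_closed_limit(self):
        # steady state at Fm': no open centres, both light ratios are 0
        acq = FRRfAcquisition(F0=0.3, Fm=1.0, F0p=0.3, Fp=0.9, Fmp=0.9,
                              sigma_psii=400, E=500)
        y = derive_yields(acq)
        assert y.FqpFvp == 0.0 and y.FqpFmp == 0.0

    def test_degenerate_denominator_raises(self):
        with pytest.raises(InvalidAcquisitionError):
            FRRfAcquisition(F0=0.5, Fm=0.5, sigma_psii=400, E=0)
        acq = FRRfAcquisition(F0=0.3, Fm=1.0, F0p=0.4, Fp=0.4, Fmp=0.4,
                              sigma_psii=400, E=10)
        with pytest.raises(InvalidAcquisitionError):
            derive_yields(acq)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_yields_bounded_for_valid_acquisitions(self, seed):
        """Ratio outputs stay in [0, 1] whenever the yield ordering holds."""
        acq = random_acquisition(np.random.default_rng(seed))
        y = derive_yields(acq)
        for v in (y.FvFm, y.FqpFmp, y.FqpFvp):
            assert 0.0 <= v <= 1.0
        if acq.F0p <= acq.Fp:
            assert y.FqpFmp <= y.FqpFvp + 1e-12


class TestSpectralCorrection:
    @pytest.mark.parametrize(
        "sigma,mode,factor,expected",
        [(875.0, "scalar", 1.75, 500.0), (300.0, "none", 1.0, 300.0),
         (300.0, "scalar", 1.5, 200.0)],
    )
    def test_modes(self, sigma, mode, factor, expected):
        corr = SpectralCorrection(mode=mode, factor=factor)
        assert correct_sigma(sigma, corr) == pytest.approx(expected)

    def test_measured_mode_applies_multiplier(self):
        corr = SpectralCorrection(mode="measured", factor=1.0)
        assert correct_sigma(400.0, corr, multiplier=1.2) == pytest.approx(480.0)
        with pytest.raises(ValueError):
            correct_sigma(400.0, corr)

    def test_bad_configuration(self):
        with pytest.raises(ValueError):
            SpectralCorrection(mode="scalar", factor=0.0)
        with pytest.raises(ValueError):
            SpectralCorrection(mode="none", factor=1.75)


class TestUnitConstant:
    def test_matches_conventional_value_to_3sf(self):
        assert unit_conversion_factor() == pytest.approx(2.43e-5, rel=5e-3)

    def test_first_principles_oracle(self):
        # independent unit analysis: Avogadro x 1e-20 m2/A2 x 3600 s/h
        # x 1e-6 mol/umol / molar mass of chl a in mg
        oracle = 6.02214076e23 * 1e-20 * 3600 * 1e-6 / 893_500.0
        assert unit_conversion_factor() == pytest.approx(oracle, rel=1e-12)
        assert unit_conversion_factor() / 2.43e-5 == pytest.approx(1.0, abs=0.01)

    def test_configurable_molar_mass(self):
        assert unit_conversion_factor(CHLA_MOLAR_MASS_MG * 2) == pytest.approx(
            unit_conversion_factor() / 2
        )


class TestNPsii:
    @pytest.mark.parametrize(
        "mode,value,expected",
        [(NPsiiMode.CONSTANT_EUKARYOTE, None, 0.0020),
         (NPsiiMode.CONSTANT_PROKARYOTE, None, 0.0030),
         (NPsiiMode.MEASURED, 0.0056, 0.0056)],
    )
    def test_resolution(self, mode, value, expected):
        assert resolve_npsii(NPsiiSpec(mode=mode, value=value)) == expected

    def test_measured_without_value_raises(self):
        with pytest.raises(ValueError):
            resolve_npsii(NPsiiSpec(mode=NPsiiMode.MEASURED))

    def test_out_of_range_warns_not_errors(self):
        with pytest.warns(UserWarning, match="plausible range"):
            v = resolve_npsii(NPsiiSpec(mode=NPsiiMode.EXTERNAL_ALGORITHM, value=0.009))
        assert v == 0.009


class TestETR:
    def test_light_dark_hand_arithmetic(self):
        acq = FRRfAcquisition(F0=0.3, Fm=1.0, F0p=0.3, Fp=0.65, Fmp=1.0,
                              sigma_psii=500.0, E=100.0)
        y = derive_yields(acq)  # FqpFvp = 0.35/0.7 = 0.5
        rec = etr_light_dark(acq, y, npsii=0.002)
        expected = 100 * 500 * 0.5 * 0.002 * unit_conversion_factor()
        assert rec.etr == pytest.approx(expected, rel=1e-12)
        assert rec.etr == pytest.approx(1.213e-3, rel=1e-3)

    def test_dark_reference_hand_arithmetic(self):
        # FqpFmp/FvFm = 0.325/0.65 = 0.5
        acq = FRRfAcquisition(F0=0.35, Fm=1.0, F0p=0.30, Fp=0.675, Fmp=1.0,
                              sigma_psii=400.0, E=100.0)
        y = derive_yields(acq)
        assert y.FqpFmp == pytest.approx(0.325)
        rec = etr_dark_reference(acq, y, npsii=0.002)
        assert rec.etr == pytest.approx(100 * 400 * 0.5 * 0.002 * unit_conversion_factor())
        assert rec.etr == pytest.approx(9.70e-4, rel=1e-3)

    def test_zero_irradiance_zero_etr(self, acquisition):
        acq = FRRfAcquisition(F0=0.3, Fm=1.0, F0p=0.28, Fp=0.6, Fmp=0.9,
                              sigma_psii=450.0, E=0.0)
        y = derive_yields(acq)
        assert etr_light_dark(acq, y, 0.002).etr == 0.0
        assert etr_dark_reference(acq, y, 0.002).etr == 0.0

    @pytest.mark.parametrize("factor", [2.0, 0.5, 10.0])
    def test_linearity_in_E_npsii_phirc(self, acquisition, factor):
        y = derive_yields(acquisition)
        base = etr_light_dark(acquisition, y, 0.002).etr
        scaled_E = FRRfAcquisition(
            F0=acquisition.F0, Fm=acquisition.Fm, F0p=acquisition.F0p,
            Fp=acquisition.Fp, Fmp=acquisition.Fmp,
            sigma_psii=acquisition.sigma_psii,
            sigma_psii_p=acquisition.sigma_psii_p, E=acquisition.E * factor,
        )
        assert etr_light_dark(scaled_E, y, 0.002).etr == pytest.approx(base * factor)
        assert etr_light_dark(acquisition, y, 0.002 * factor).etr == pytest.approx(base * factor)
        assert etr_light_dark(acquisition, y, 0.002, phi_RC=factor).etr == pytest.approx(base * factor)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_no_npq_equivalence_property(self, seed):
        """With Fm'=Fm, F0'=F0, sigma'=sigma the two variants agree exactly:
        (Fm−F')/Fm · Fm/(Fm−F0) = (Fm−F')/(Fm−F0)."""
        acq = random_acquisition(np.random.default_rng(seed), no_npq=True)
        y = derive_yields(acq)
        a = etr_light_dark(acq, y, 0.002).etr
        b = etr_dark_reference(acq, y, 0.002).etr
        assert a == pytest.approx(b, rel=1e-12, abs=1e-18)

    def test_missing_light_yields_directs_to_other_variant(self):
        acq = FRRfAcquisition(F0=0.3, Fm=1.0, sigma_psii=400, E=100)
        y = derive_yields(acq)
        with pytest.raises(InvalidAcquisitionError, match="dark_reference"):
            etr_light_dark(acq, y, 0.002)

    def test_sigma_light_defaults_to_dark_chamber(self):
        acq = FRRfAcquisition(F0=0.3, Fm=1.0, F0p=0.28, Fp=0.6, Fmp=0.9,
                              sigma_psii=480.0, E=100)
        assert acq.sigma_light == 480.0
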