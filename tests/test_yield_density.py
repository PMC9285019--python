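import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covermix.data_model import (
    BICULTURE_PROPORTIONS,
    MONOCULTURE_PROPORTIONS,
    PlotObservation,
)
from covermix.yield_density import (
    BicultureFit,
    FitError,
    fit_biculture,
    fit_monoculture,
    fits_to_frame,
    frame_to_fits,
    linearized_fit,
    predict_biculture,
    predict_monoculture,
)

REC = {"M": 292, "S": 218}


def mono_obs(b0, b11, species="M", noise=None, rng=None, estab=1.0):
    """Monoculture plots at the eight standard proportions, exact model biomass."""
    out = []
    for i, p in enumerate(MONOCULTURE_PROPORTIONS):
        n = p * REC[species]
        if rng is not None and estab < 1:
            n = float(rng.binomial(round(n), estab))
        y = float(predict_monoculture(b0, b11, n))
        if noise is not None:
            y *= noise(i)
        out.append(
            PlotObservation(f"m{i}", "SY1", "1", frozenset({species}), {species: n}, {species: y})
        )
    return out


def bi_obs(b0, b11, b12, focal="M", companion="S", noise=None):
    """Focal monocultures plus the eight biculture combinations.

    Noise (a callable of the plot index) applies to every stratum, matching
    how field noise would hit the whole response surface.
    """
    out = []
    rates = [(p * REC[focal], 0.0) for p in MONOCULTURE_PROPORTIONS] + [
        (pf * REC[focal], pc * REC[companion]) for pf, pc in BICULTURE_PROPORTIONS
    ]
    for i, (n1, n2) in enumerate(rates):
        y = float(predict_biculture(b0, b11, b12, n1, n2))
        if noise is not None:
            y *= noise(i)
        species = frozenset({focal}) if n2 == 0 else frozenset({focal, companion})
        density = {focal: n1} if n2 == 0 else {focal: n1, companion: n2}
        biomass = {focal: y} if n2 == 0 else {focal: y, companion: 1.0}
        out.append(PlotObservation(f"p{i}", "SY1", "1", species, density, biomass))
    return out


def mono_obs_pair(b0, b11, focal):
    # monoculture stratum consistent with the biculture surface (N2 = 0)
    out = []
    for i, p in enumerate(MONOCULTURE_PROPORTIONS):
        n = p * REC[focal]
        y = float(predict_monoculture(b0, b11, n))
        out.append(
            PlotObservation(f"m{i}", "SY1", "1", frozenset({focal}), {focal: n}, {focal: y})
        )
    return out


class TestPrediction:
    def test_monoculture_point_value(self):
        # direct evaluation of the hyperbola
        assert predict_monoculture(0.0491, 0.0018511, 218) == pytest.approx(481.6, abs=0.1)

    def test_zero_density_gives_zero(self):
        assert predict_monoculture(0.1, 0.002, 0.0) == 0.0
        assert predict_biculture(0.1, 0.002, 0.005, 0.0, 50.0) == 0.0

    def test_asymptote_is_inverse_intraspecific(self):
        # law of constant final yield, checked numerically at N = 1e6
        assert predict_monoculture(0.0491, 0.0018511, 1e6) == pytest.approx(
            1 / 0.0018511, rel=1e-3
        )
        assert 1 / 0.0018511 == pytest.approx(540.2, abs=0.1)

    def test_biculture_reduces_to_monoculture(self):
        b0, b11, b12 = 0.1319, 0.00280947, 0.00820418
        assert predict_biculture(b0, b11, b12, 146, 0) == pytest.approx(
            predict_monoculture(b0, b11, 146)
        )
        assert predict_biculture(b0, b11, b12, 146, 0) == pytest.approx(269.3, abs=0.1)

    def test_biculture_point_value(self):
        assert predict_biculture(
            0.1319, 0.00280947, 0.00820418, 146, 109
        ) == pytest.approx(101.6, abs=0.1)

    @given(
        b0=st.floats(0.01, 1),
        b11=st.floats(1e-4, 0.1),
        b12=st.floats(1e-4, 0.1),
        n1=st.floats(1, 500),
        n2=st.floats(0, 500),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotonicity(self, b0, b11, b12, n1, n2):
        """Y increases in own density, decreases in companion density;
        per-plant weight decreases in both."""
        eps = 1e-3
        y = predict_biculture(b0, b11, b12, n1, n2)
        assert predict_biculture(b0, b11, b12, n1 + eps, n2) > y
        assert predict_biculture(b0, b11, b12, n1, n2 + eps) < y
        w = y / n1
        assert predict_biculture(b0, b11, b12, n1 + eps, n2) / (n1 + eps) < w


class TestLinearizedFit:
    def test_exact_on_noiseless_biculture(self):
        obs = bi_obs(0.1, 0.002, 0.005)
        beta = linearized_fit(obs, "M", "S")
        assert beta == pytest.approx([0.1, 0.002, 0.005], rel=1e-10)

    def test_monoculture_reduced_design(self):
        obs = mono_obs(0.16, 0.00212)
        beta = linearized_fit(obs, "M")
        assert len(beta) == 2
        assert beta == pytest.approx([0.16, 0.00212], rel=1e-10)

    def test_underdetermined_raises(self):
        obs = mono_obs(0.16, 0.00212)[:1]
        with pytest.raises(FitError):
            linearized_fit(obs, "M")


class TestNonlinearFit:
    def test_noiseless_monoculture_recovery(self):
        fit = fit_monoculture(mono_obs(0.16, 0.00212), "M")
        assert fit.b0 == pytest.approx(0.16, rel=1e-6)
        assert fit.b11 == pytest.approx(0.00212, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.n_obs == 8

    def test_noiseless_biculture_recovery(self):
        obs = bi_obs(0.1319, 0.00280947, 0.00820418)
        fit = fit_biculture(obs, "M", "S")
        assert fit.b0 == pytest.approx(0.1319, rel=1e-6)
        assert fit.b11 == pytest.approx(0.00280947, rel=1e-6)
        assert fit.b12 == pytest.approx(0.00820418, rel=1e-6)

    def test_linearized_and_nonlinear_agree_noiseless(self):
        obs = bi_obs(0.2, 0.003, 0.001)
        beta = linearized_fit(obs, "M", "S")
        fit = fit_biculture(obs, "M", "S")
        assert [fit.b0, fit.b11, fit.b12] == pytest.approx(list(beta), rel=1e-6)

    def test_degenerate_equal_densities(self):
        obs = [
            PlotObservation(f"p{i}", "SY1", "1", frozenset("M"), {"M": 100.0}, {"M": 200.0})
            for i in range(5)
        ]
        with pytest.raises(FitError):
            fit_monoculture(obs, "M")

    def test_companion_never_present_flags_boundary(self):
        # b12 unidentifiable when the companion density is always zero
        obs = mono_obs_pair(0.1, 0.002, "M")
        with pytest.warns(UserWarning):
            fit = fit_biculture(obs, "M", "S")
        assert fit.boundary

    def test_noisy_monoculture_recovery(self):
        """10% multiplicative noise, n=8: b11 is recovered with median
        absolute relative error well under 25% over 200 replicates."""
        b0, b11 = 0.1336, 0.1336 * 0.0210
        errs = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            obs = mono_obs(b0, b11, noise=lambda i: rng.lognormal(0, 0.1), rng=rng, estab=0.8)
            fit = fit_monoculture(obs, "M")
            errs.append((fit.b11 - b11) / b11)
        assert np.median(np.abs(errs)) < 0.25

    def test_interspecific_interval_coverage(self):
        """95% Wald intervals for b12 cover the truth 88-99% of the time
        under 10% noise (200 replicates, fixed seeds)."""
        b0, b11, b12 = 0.1319, 0.00280947, 0.00820418
        cover = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(7000 + rep)
            obs = bi_obs(b0, b11, b12, noise=lambda i: rng.lognormal(0, 0.1))
            fit = fit_biculture(obs, "M", "S")
            lo = fit.b12 - 1.96 * fit.se["b12"]
            hi = fit.b12 + 1.96 * fit.se["b12"]
            cover += lo <= b12 <= hi
        assert 0.88 <= cover / reps <= 0.99


class TestSerialization:
    def test_frame_roundtrip(self):
        fits = [
            fit_monoculture(mono_obs(0.16, 0.00212), "M"),
            fit_biculture(bi_obs(0.1319, 0.00280947, 0.00820418), "M", "S"),
        ]
        df = fits_to_frame(fits)
        assert set(df["treatment"]) == {"M", "MS"}
        assert df.loc[df.treatment == "MS", "b12_over_b0"].iloc[0] == pytest.approx(
            0.0622, rel=1e-4
        )
        back = frame_to_fits(df)
        assert isinstance(back[1], BicultureFit)
        assert back[1].b12 == pytest.approx(fits[1].b12)
        assert back[0].coefficients == pytest.approx(fits[0].coefficients)
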