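"""Ring-series processing: BAI geometry, detrending/prewhitening behaviour,
robust chronologies, drought-response ratios and bootstrap correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinedrought import dendro
from pinedrought.dendro import (
    biweight_mean,
    build_chronology,
    climate_growth_correlation,
    conduit_reinforcement,
    detrend_spline,
    lloret_indices,
    prewhiten_ar1,
    rw_to_bai,
)


class TestBAI:
    def test_unit_rings_give_circle_area_increments(self):
        rw = pd.Series([1.0, 1.0], index=[2000, 2001])
        bai = rw_to_bai(rw)
        np.testing.assert_allclose(bai.to_numpy(), [np.pi, 3 * np.pi])

    @given(
        widths=st.lists(st.floats(0.1, 5.0), min_size=2, max_size=40),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bai_telescopes_to_total_area(self, widths):
        bai = rw_to_bai(np.array(widths))
        r = sum(widths)
        assert bai.sum() == pytest.approx(np.pi * r * r, rel=1e-9)

    def test_bark_anchor_with_exact_radius_matches_pith(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.2, 3.0, 25)
        pith = rw_to_bai(w, anchor="pith")
        bark = rw_to_bai(w, anchor="bark", outer_radius=float(w.sum()))
        np.testing.assert_allclose(pith.to_numpy(), bark.to_numpy(), rtol=1e-9)

    def test_bark_radius_smaller_than_rings_rejected(self):
        with pytest.raises(ValueError, match="outer radius"):
            rw_to_bai(np.array([1.0, 1.0]), anchor="bark", outer_radius=1.5)

    def test_nonpositive_widths_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rw_to_bai(np.array([1.0, 0.0]))


class TestDetrend:
    def test_constant_series_gives_unit_index(self):
        idx = detrend_spline(np.full(30, 7.3))
        np.testing.assert_allclose(idx.to_numpy(), 1.0, atol=1e-9)

    def test_linear_trend_removed(self):
        """A flexible spline on a pure linear trend leaves a flat unit index
        (mean 1, no significant residual slope)."""
        y = np.linspace(1.0, 3.0, 60)
        idx = detrend_spline(y, stiffness=15).to_numpy()
        assert idx.mean() == pytest.approx(1.0, abs=0.01)
        t = np.arange(60)
        slope, intercept = np.polyfit(t, idx, 1)
        resid = idx - (slope * t + intercept)
        se = np.sqrt(resid.var(ddof=2) / ((t - t.mean()) ** 2).sum())
        assert abs(slope) / se < 2.0  # slope not significant

    def test_ratio_detrending_index_mean_near_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(25, 60)
            y = (
                2.0 * np.exp(-0.03 * np.arange(n))
                + 0.5
                + rng.normal(0, 0.1, n)
            )
            idx = detrend_spline(y)
            assert idx.mean() == pytest.approx(1.0, abs=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="10 years"):
            detrend_spline(np.ones(5))

    def test_fifty_percent_frequency_response_at_cutoff(self):
        """The smoother passes exactly half of a sinusoid at the stiffness
        wavelength (boundary effects excluded)."""
        n, wavelength = 400, 30
        t = np.arange(n)
        y = np.sin(2 * np.pi * t / wavelength)
        from pinedrought.dendro import _smoothing_spline

        f = _smoothing_spline(y, wavelength)
        core = slice(100, 300)
        gain = np.sqrt(np.mean(f[core] ** 2) / np.mean(y[core] ** 2))
        assert gain == pytest.approx(0.5, abs=0.03)


class TestPrewhiten:
    def test_white_noise_passes_through(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.0, 0.1, 200)
        out = prewhiten_ar1(x).to_numpy()
        assert np.max(np.abs(out - x)) < 0.05

    def test_ar1_autocorrelation_removed(self):
        rng = np.random.default_rng(3)
        n = 500
        e = np.zeros(n)
        for t in range(1, n):
            e[t] = 0.7 * e[t - 1] + rng.normal(0, 0.1)
        out = prewhiten_ar1(e + 1.0).to_numpy()
        rho1 = np.corrcoef(out[1:], out[:-1])[0, 1]
        assert abs(rho1) < 0.1

    def test_constant_series_returned_unchanged(self):
        x = np.full(20, 3.0)
        np.testing.assert_allclose(prewhiten_ar1(x).to_numpy(), x)

    def test_mean_preserved(self):
        rng = np.random.default_rng(4)
        x = 1.0 + 0.1 * rng.standard_normal(50)
        assert prewhiten_ar1(x).mean() == pytest.approx(x.mean(), abs=1e-10)


class TestChronology:
    def test_symmetric_values_average_to_center(self):
        assert biweight_mean(np.array([0.9, 1.0, 1.1])) == pytest.approx(1.0)

    def test_outlier_downweighted_against_direct_iteration(self):
        """Biweight on [1,1,1,10] stays near 1, below the arithmetic mean,
        and matches a from-scratch textbook iteration."""
        x = np.array([1.0, 1.0, 1.0, 10.0])
        bw = biweight_mean(x)
        assert bw < x.mean()
        assert 0.99 <= bw <= 1.05

        # independent textbook iteration
        m = np.median(x)
        for _ in range(100):
            mad = np.median(np.abs(x - m))
            if mad == 0:
                break
            u = (x - m) / (9 * mad)
            w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            m = np.sum(w * x) / np.sum(w)
        assert bw == pytest.approx(m, abs=1e-9)

    def test_single_tree_group_equals_its_series(self):
        df = pd.DataFrame(
            {"tree": "t1", "year": [2000, 2001, 2002], "value": [0.9, 1.1, 1.0]}
        )
        chron = build_chronology(df, groups={"t1": "f1"})
        np.testing.assert_allclose(chron["index"], [0.9, 1.1, 1.0])
        assert (chron["depth"] == 1).all()

    def test_start_year_drops_juvenile_years(self):
        df = pd.DataFrame(
            {"tree": "t1", "year": [1985, 1990, 1995], "value": [1.0, 1.0, 1.0]}
        )
        chron = build_chronology(df, start_year=1990)
        assert chron["year"].min() == 1990

    def test_missing_group_mapping_rejected(self):
        df = pd.DataFrame({"tree": ["a", "b"], "year": 2000, "value": 1.0})
        with pytest.raises(ValueError, match="without a group"):
            build_chronology(df, groups={"a": "f1"})


class TestLloret:
    def test_toy_arithmetic(self):
        bai = pd.Series(
            [10, 10, 10, 5, 5, 8, 8, 8],
            index=[1999, 2000, 2001, 2002, 2003, 2004, 2005, 2006],
            dtype=float,
        )
        res = lloret_indices(bai, (2002, 2003), pre_window=3, post_window=3)
        assert res["RS"] == pytest.approx(0.5)
        assert res["RC"] == pytest.approx(1.6)
        assert res["RL"] == pytest.approx(0.8)

    def test_constant_bai_gives_unit_ratios(self):
        bai = pd.Series(4.0, index=range(1995, 2010))
        res = lloret_indices(bai, (2002, 2003))
        assert res["RS"] == res["RC"] == res["RL"] == 1.0

    @given(
        vals=st.lists(st.floats(0.5, 50.0), min_size=9, max_size=9),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_resilience_identity(self, vals):
        bai = pd.Series(vals, index=range(1999, 2008))
        res = lloret_indices(bai, (2002, 2003))
        assert res["RL"] == pytest.approx(res["RS"] * res["RC"], rel=1e-12)

    def test_missing_window_years_listed(self):
        bai = pd.Series(1.0, index=range(2000, 2006))
        with pytest.raises(ValueError, match="1999"):
            lloret_indices(bai, (2002, 2003), pre_window=3, post_window=2)


class TestConduitReinforcement:
    def test_arithmetic(self):
        cwr, cwrr = conduit_reinforcement([2.0], [20.0], [20.0])
        assert cwr[0] == pytest.approx(0.01)
        assert cwrr[0] == pytest.approx(0.01)
        cwr, cwrr = conduit_reinforcement([2.0], [10.0], [30.0])
        assert cwr[0] == pytest.approx(0.01)
        assert cwrr[0] == pytest.approx(0.04)

    def test_scale_invariance(self):
        cwr1, _ = conduit_reinforcement([2.0], [15.0], [25.0])
        cwr2, _ = conduit_reinforcement([6.0], [45.0], [75.0])
        assert cwr1[0] == pytest.approx(cwr2[0], rel=1e-12)

    def test_zero_lumen_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            conduit_reinforcement([2.0], [0.0], [20.0])


class TestCorrelationFunction:
    @staticmethod
    def _climate(years, seed=0):
        rng = np.random.default_rng(seed)
        rows = [
            (y, m, rng.standard_normal())
            for y in range(years[0] - 1, years[-1] + 1)
            for m in range(1, 13)
        ]
        return pd.DataFrame(rows, columns=["year", "month", "spei"])

    def test_self_correlation_is_one_and_significant(self):
        years = list(range(1990, 2012))
        clim = self._climate(years, seed=1)
        june = clim[(clim["month"] == 6)].set_index("year")["spei"]
        chron = pd.Series(june.loc[years].to_numpy(), index=years)
        out = climate_growth_correlation(
            chron, clim, "spei", months=((6, 0), (7, 0)), n_boot=500, seed=2
        )
        row = out[(out["month"] == 6) & (out["lag"] == 0)].iloc[0]
        assert row["coef"] == pytest.approx(1.0, abs=1e-12)
        assert bool(row["significant"])

    def test_month_labels_case_convention(self):
        assert dendro.month_label(6, 0) == "JUN"
        assert dendro.month_label(6, -1) == "jun"

    def test_short_overlap_rejected(self):
        years = list(range(2000, 2010))
        clim = self._climate(years)
        chron = pd.Series(1.0, index=years)
        with pytest.raises(ValueError, match="15"):
            climate_growth_correlation(chron, clim, "spei", n_boot=100, seed=0)

    def test_recovers_generating_sensitivity_sign(self):
        """A chronology built with positive dependence on June climate shows
        a positive, significant June coefficient."""
        years = list(range(1988, 2012))
        clim = self._climate(years, seed=3)
        june = clim[clim["month"] == 6].set_index("year")["spei"]
        rng = np.random.default_rng(4)
        chron = pd.Series(
            0.9 * june.loc[years].to_numpy() + 0.4 * rng.standard_normal(len(years)),
            index=years,
        )
        out = climate_growth_correlation(chron, clim, "spei", n_boot=1000, seed=5)
        row = out[(out["month"] == 6) & (out["lag"] == 0)].iloc[0]
        assert row["coef"] > 0.5
        assert bool(row["significant"])


def test_detrend_prewhiten_biweight_chain_trend_free():
    """The full chain on trend-free white noise returns a chronology
    uncorrelated with calendar year."""
    rng = np.random.default_rng(6)
    years = np.arange(1990, 2012)
    frames = []
    for t in range(12):
        y = 1.0 + 0.15 * rng.standard_normal(len(years))
        res = prewhiten_ar1(detrend_spline(pd.Series(y, index=years)))
        frames.append(
            pd.DataFrame({"tree": f"t{t}", "year": years, "value": res.to_numpy()})
        )
    chron = build_chronology(pd.concat(frames))
    r = np.corrcoef(chron["year"], chron["index"])[0, 1]
    assert abs(r) < 0.15
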