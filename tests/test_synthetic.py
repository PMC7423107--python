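"""Generative model: survey designs, latent fields, observations."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from reefbarrens import synthetic, terrain
from reefbarrens.stmodel import spatial_correlation
from reefbarrens.synthetic import (
    DesignConfig,
    ObservationConfig,
    SimulationTruth,
    make_bathymetry,
    make_survey_design,
    simulate_latent_field,
    simulate_observations,
)


def tiny_design(**kw):
    defaults = dict(
        n_sites=2, site_centres=((50.0, 50.0), (250.0, 50.0)),
        ntr_site_index=1, lines_per_site=1, line_length_m=20.0,
        image_spacing_m=2.0,
    )
    defaults.update(kw)
    return make_survey_design(DesignConfig(**defaults))


def tiny_truth(**kw):
    defaults = dict(beta=(0.0,) * 7, rho=17.0, sigma=3.413, phi=0.734, seed=0)
    defaults.update(kw)
    return SimulationTruth(**defaults)


class TestBathymetry:
    def test_constant_depth(self):
        g = make_bathymetry(extent=(60, 60), depth_amplitude=0.0,
                            roughness_patch_params={"n_patches": 0}, seed=1)
        assert np.all(g.values == 25.0)

    def test_deterministic(self):
        a = make_bathymetry(extent=(80, 80), seed=42)
        b = make_bathymetry(extent=(80, 80), seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_smooth_surface_has_negligible_vrm(self):
        g = make_bathymetry(extent=(80, 80), smooth_scale=60.0,
                            roughness_patch_params={"n_patches": 0}, seed=3)
        v = terrain.vrm(g, 3).values
        assert np.nanmax(v) < 0.01

    def test_depth_positive_and_plausible(self):
        g = make_bathymetry(seed=5)
        assert g.values.min() > 0
        assert 5 <= g.values.mean() <= 45

    def test_nodata_margin(self):
        g = make_bathymetry(extent=(60, 60), nodata_margin=4, seed=2)
        assert g.nodata_mask[:4].all() and g.nodata_mask[:, -4:].all()
        assert not g.nodata_mask[10:-10, 10:-10].any()

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_bathymetry(extent=(2, 2), cell_size=1.0)


class TestSurveyDesign:
    def test_straight_transect_arithmetic(self):
        d = make_survey_design(DesignConfig(
            n_sites=1, site_centres=((50.0, 50.0),), ntr_site_index=0,
            lines_per_site=1, line_length_m=10.0, image_spacing_m=1.0,
        ))
        pts = d.image_points
        assert len(pts) == 11
        assert pts["seq_index"].tolist() == list(range(11))
        assert np.allclose(np.diff(np.sort(pts["x_m"])), 1.0)

    def test_ntr_years_superset(self):
        d = make_survey_design(DesignConfig())
        ntr = d.sites.loc[d.sites["ntr"], "site_id"].iloc[0]
        ntr_years = set(d.years[ntr])
        for sid, ys in d.years.items():
            if sid != ntr:
                assert set(ys) < ntr_years
                assert set(ys) == {2011, 2013, 2016}
        assert 2014 in ntr_years

    def test_exactly_one_ntr_by_default(self):
        d = make_survey_design(DesignConfig())
        assert d.sites["ntr"].sum() == 1

    def test_deterministic(self):
        a = make_survey_design(DesignConfig())
        b = make_survey_design(DesignConfig())
        pd.testing.assert_frame_equal(a.image_points, b.image_points)

    def test_spacing_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="empty design"):
            make_survey_design(DesignConfig(
                line_length_m=5.0, image_spacing_m=10.0
            ))


class TestLatentField:
    def test_sigma_zero_field_is_zero(self):
        lf = simulate_latent_field(tiny_design(), tiny_truth(sigma=0.0))
        assert np.all(lf.z == 0.0)

    def test_ar_recursion_exact(self):
        truth = tiny_truth()
        lf = simulate_latent_field(tiny_design(), truth)
        np.testing.assert_allclose(
            lf.z[:, 1:], truth.phi * lf.z[:, :-1] + lf.omega[:, 1:], atol=1e-12
        )

    def test_reproducible_given_seed(self):
        d = tiny_design()
        a = simulate_latent_field(d, tiny_truth())
        b = simulate_latent_field(d, tiny_truth())
        np.testing.assert_array_equal(a.z, b.z)

    def test_phi_zero_years_independent(self):
        # across 500 replicates the lag-1 correlation at a fixed point
        # should vanish
        d, truth = tiny_design(), tiny_truth(phi=0.0)
        rng = np.random.default_rng(11)
        pairs = np.array([
            simulate_latent_field(d, truth, rng=rng).z[3, :2] for _ in range(500)
        ])
        r = np.corrcoef(pairs.T)[0, 1]
        assert abs(r) < 0.1

    def test_stationary_variance_identity(self):
        # Var z(s, 1) = sigma^2 / (1 - phi^2) within 10% over 500 replicates
        d, truth = tiny_design(), tiny_truth()
        rng = np.random.default_rng(21)
        z1 = np.array([
            simulate_latent_field(d, truth, rng=rng).z[3, 0] for _ in range(500)
        ])
        target = truth.sigma**2 / (1 - truth.phi**2)
        assert abs(z1.var(ddof=1) - target) / target < 0.10

    def test_variance_constant_across_years(self):
        d, truth = tiny_design(), tiny_truth()
        rng = np.random.default_rng(31)
        z = np.array([
            simulate_latent_field(d, truth, rng=rng).z[3] for _ in range(500)
        ])
        target = truth.sigma**2 / (1 - truth.phi**2)
        for t in range(z.shape[1]):
            assert abs(z[:, t].var(ddof=1) - target) / target < 0.15

    def test_separability(self):
        # corr(z(s,t), z(s',t')) = H(d) * phi^|t-t'| at point pairs x lags
        d, truth = tiny_design(), tiny_truth()
        rng = np.random.default_rng(41)
        reps = [simulate_latent_field(d, truth, rng=rng) for _ in range(500)]
        pts = reps[0].point_index
        for (i, j) in [(0, 2), (0, 5), (3, 8)]:
            dist = float(np.hypot(pts.x_m[i] - pts.x_m[j],
                                  pts.y_m[i] - pts.y_m[j]))
            for lag in (0, 1):
                a = np.array([r.z[i, 0] for r in reps])
                b = np.array([r.z[j, lag] for r in reps])
                want = spatial_correlation(dist, truth.rho) * truth.phi**lag
                got = np.corrcoef(a, b)[0, 1]
                assert got == pytest.approx(want, abs=0.12)

    def test_coincident_points_jittered(self):
        cfg = DesignConfig(
            n_sites=1, site_centres=((50.0, 50.0),), ntr_site_index=0,
            lines_per_site=2, line_length_m=10.0, line_spacing_m=0.0,
            image_spacing_m=2.0,
        )  # two identical lines -> duplicated coordinates
        d = make_survey_design(cfg)
        lf = simulate_latent_field(d, tiny_truth())
        xy = lf.point_index[["x_m", "y_m"]].to_numpy()
        assert len(np.unique(np.round(xy, 9), axis=0)) == len(xy)


class TestObservations:
    def run_obs(self, truth, seed=0, **obs_kw):
        d = tiny_design(lines_per_site=2, line_length_m=40.0,
                        image_spacing_m=1.0)
        bathy = make_bathymetry(seed=seed)
        rug = terrain.vrm(bathy, 3)
        lf = simulate_latent_field(d, truth, rng=np.random.default_rng(seed))
        return simulate_observations(
            d, truth, lf, bathy, rug,
            obs_config=ObservationConfig(**obs_kw) if obs_kw else None,
            rng=np.random.default_rng(seed + 1),
        )

    def test_beta_zero_sigma_zero_gives_half(self):
        rec = self.run_obs(tiny_truth(sigma=0.0), seed=2)
        n = len(rec)
        assert abs(rec["barren_true"].mean() - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_intercept_only_probability(self):
        # intercept -7.478, all other coefficients zero: per-image
        # probability is the inverse logit ~ 5.6e-4 regardless of covariates
        truth = tiny_truth(beta=(-7.478, 0, 0, 0, 0, 0, 0), sigma=0.0)
        rec = self.run_obs(truth, seed=3)
        assert np.allclose(rec["p_true"], expit(-7.478))
        assert expit(-7.478) == pytest.approx(5.6e-4, rel=0.02)

    def test_deterministic(self):
        a = self.run_obs(tiny_truth(), seed=5)
        b = self.run_obs(tiny_truth(), seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_classification_recovers_truth(self):
        from reefbarrens import imagefilter

        rec = self.run_obs(tiny_truth(beta=(-1.0, 0, 0, 0, 0, 0, 0)), seed=6)
        out = imagefilter.classify_barrens(rec)
        assert (out["barren"] == out["barren_true"]).all()

    def test_adjacency_branch_exercised(self):
        rec = self.run_obs(tiny_truth(beta=(0.5, 0, 0, 0, 0, 0, 0)), seed=7)
        barren = rec["barren_true"].to_numpy()
        urch = rec["urchin_present"].to_numpy()
        assert (barren & ~urch).any()  # some barrens rely on a neighbour

    def test_sand_fraction_excludable(self):
        rec = self.run_obs(tiny_truth(), seed=8, sand_fraction=0.3)
        frac = (rec["pct_sand"] > 50).mean()
        assert 0.1 < frac < 0.5
        assert ((rec["pct_bare_rock"] + rec["pct_sand"]) <= 100.0 + 1e-9).all()

    def test_percent_ranges(self):
        rec = self.run_obs(tiny_truth(), seed=9)
        for col in ("pct_bare_rock", "pct_sand"):
            assert rec[col].between(0, 100).all()


class TestIO:
    def test_records_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "records.csv"
        synthetic.write_records(small_dataset["records"], path)
        back = synthetic.read_records(path)
        rec = small_dataset["records"]
        assert len(back) == len(rec)
        assert back["urchin_present"].dtype == bool
        np.testing.assert_allclose(back["depth_m"], rec["depth_m"], rtol=1e-9)

    def test_truth_round_trip(self, tmp_path):
        t = synthetic.REFERENCE_TRUTH
        path = tmp_path / "truth.txt"
        synthetic.write_truth(t, path)
        back = synthetic.read_truth(path)
        assert back == t
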