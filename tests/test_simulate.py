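"""Generator determinism, structure and slope/regime conventions."""

import numpy as np
import pandas as pd
import pytest

from reefcascade.datamodel import LocationMeta
from reefcascade.errors import ConfigError
from reefcascade.simulate import (
    LocationPlan,
    RegimeSpec,
    SimulationConfig,
    simulate_dataset,
    simulate_location,
)


def _meta(loc="L1"):
    return LocationMeta(
        location_id=loc, latitude=-20.0, exploitation_status="always_fished"
    )


def _one_location(regime, config, seed=0, **kw):
    rng = np.random.default_rng(seed)
    kw.setdefault("region", "tropical")
    kw.setdefault("n_years", 8)
    kw.setdefault("n_sites", 3)
    return simulate_location(_meta(), regime, config, rng, **kw)


class TestRegimeSpec:
    def test_top_down_slopes_alternate(self):
        s = RegimeSpec("top_down_cascade", base_slope=0.15, attenuation=0.8).slopes()
        assert s[0] == pytest.approx(0.15)
        assert s[1] == pytest.approx(-0.12)
        assert s[2] == pytest.approx(0.096)
        assert np.sign(s[0]) == -np.sign(s[1]) == np.sign(s[2])

    def test_bottom_up_slopes_share_sign_strongest_at_base(self):
        s = RegimeSpec("bottom_up", base_slope=0.2, attenuation=0.5).slopes()
        assert np.all(np.sign(s) == 1.0)
        assert s[2] > s[1] > s[0]

    def test_null_slopes_zero(self):
        assert RegimeSpec("null").slopes() == (0.0, 0.0, 0.0)

    def test_independent_draws_from_rng(self):
        rng = np.random.default_rng(0)
        s = RegimeSpec("independent", slope_sd=0.1).slopes(rng)
        assert len(s) == 3 and any(v != 0 for v in s)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            RegimeSpec("sideways")
        with pytest.raises(ConfigError):
            RegimeSpec("null", attenuation=0.0)
        with pytest.raises(ConfigError):
            SimulationConfig(rho=1.0)
        with pytest.raises(ConfigError):
            SimulationConfig(sigma_year=-0.1)


class TestSimulateLocation:
    def test_null_regime_zero_noise_constant_over_years(self):
        config = SimulationConfig(rho=0.0, sigma_year=0.0, sigma_site=0.0, sigma_obs=0.0)
        records, _ = _one_location(RegimeSpec("null"), config)
        per_site = records.groupby(["trophic_group", "site_id"])["value"].nunique()
        assert (per_site == 1).all()

    def test_same_seed_identical_output(self):
        config = SimulationConfig()
        a, truth_a = _one_location(RegimeSpec("bottom_up"), config, seed=5)
        b, truth_b = _one_location(RegimeSpec("bottom_up"), config, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert truth_a == truth_b

    def test_distinct_seeds_distinct_year_effects(self):
        config = SimulationConfig()
        _, ta = _one_location(RegimeSpec("null"), config, seed=1)
        _, tb = _one_location(RegimeSpec("null"), config, seed=2)
        assert ta["year_effects_predators"] != tb["year_effects_predators"]

    def test_algae_emitted_as_percent_cover(self):
        config = SimulationConfig()
        records, _ = _one_location(RegimeSpec("null"), config)
        kinds = records.groupby("trophic_group")["value_kind"].agg(set)
        assert kinds["algae"] == {"percent_cover"}
        assert kinds["predators"] == {"density"}

    def test_cascade_regime_recovered_by_trend_fits(self):
        """Low-noise cascade simulation yields the (+, -, +) sign pattern."""
        from reefcascade.aggregate import build_location_series
        from reefcascade.trends import fit_all_trends

        config = SimulationConfig(
            rho=0.0, sigma_year=0.02, sigma_site=0.1, sigma_obs=0.05
        )
        regime = RegimeSpec("top_down_cascade", base_slope=0.15, attenuation=0.8)
        records, truth = _one_location(regime, config, seed=3, n_years=15)
        meta = pd.DataFrame(
            [{"location_id": "L1", "latitude": -20.0,
              "exploitation_status": "always_fished",
              "reserve_start_year": np.nan, "analysis_start_year": np.nan}]
        )
        _, replicates, _ = build_location_series(records, meta)
        results = {t.trophic_group: t for t in fit_all_trends(replicates)}
        assert results["predators"].direction == "increasing"
        assert results["herbivores"].direction == "decreasing"
        assert results["algae"].direction == "increasing"
        assert np.sign(results["predators"].slope) == np.sign(truth["beta_predators"])


class TestSimulateDataset:
    def test_default_dataset_structure(self, default_dataset):
        records, meta, truth = default_dataset
        assert len(truth) == 104 and len(meta) == 104
        n_series = records.groupby(["location_id", "trophic_group"]).ngroups
        assert n_series == 312
        # study-like composition of forced regimes
        counts = truth["regime"].value_counts()
        assert counts["top_down_cascade"] == 4
        assert counts["bottom_up"] == 20

    def test_single_location_ledger(self):
        cfg = SimulationConfig(n_locations=1, seed=0)
        _, meta, truth = simulate_dataset(cfg)
        assert len(truth) == 1 and len(meta) == 1

    def test_dataset_determinism_under_fixed_seed(self):
        a = simulate_dataset(SimulationConfig(n_locations=6, seed=42))
        b = simulate_dataset(SimulationConfig(n_locations=6, seed=42))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_duplicate_location_ids_rejected(self):
        cfg = SimulationConfig(n_locations=2, seed=0)
        plan = LocationPlan(
            meta=_meta(), region="tropical", regime=RegimeSpec("null"),
            n_years=5, n_sites=3,
        )
        cfg.plans = [plan, plan]
        with pytest.raises(ConfigError, match="duplicate"):
            simulate_dataset(cfg)

    def test_slope_consistency_long_low_noise_series(self):
        """Sample log-slope approaches the latent slope as T grows."""
        cfg = SimulationConfig(
            n_locations=1, rho=0.0, sigma_year=0.01, sigma_site=0.0,
            sigma_obs=0.0, seed=1, min_years=19, max_years=19,
        )
        cfg.plans = [
            LocationPlan(
                meta=_meta(), region="tropical",
                regime=RegimeSpec("bottom_up", base_slope=0.1, attenuation=1.0),
                n_years=19, n_sites=3,
            )
        ]
        records, _, truth = simulate_dataset(cfg)
        sub = records[records["trophic_group"] == "algae"]
        annual = np.log(sub.groupby("year")["value"].mean())
        years = annual.index.to_numpy(dtype=float)
        slope = np.polyfit(years - years.mean(), annual.to_numpy(), 1)[0]
        assert slope == pytest.approx(0.1, abs=0.01)

    def test_ha_innovation_correlation_imprints_on_year_effects(self):
        pos, neg = [], []
        for corr, bag in ((0.9, pos), (-0.9, neg)):
            for seed in range(30):
                cfg = SimulationConfig(
                    n_locations=1, rho=0.0, sigma_year=0.3, sigma_site=0.0,
                    sigma_obs=0.0, seed=seed, min_years=19, max_years=19,
                )
                cfg.plans = [
                    LocationPlan(
                        meta=_meta(), region="tropical",
                        regime=RegimeSpec("null", ha_innovation_corr=corr),
                        n_years=19, n_sites=3,
                    )
                ]
                _, _, truth = simulate_dataset(cfg)
                uh = np.array(truth["year_effects_herbivores"][0].split(";"), dtype=float)
                ua = np.array(truth["year_effects_algae"][0].split(";"), dtype=float)
                bag.append(np.corrcoef(uh, ua)[0, 1])
        assert np.mean(pos) > 0.5 > -0.5 > np.mean(neg)


def test_config_file_round_trip(tmp_path):
    cfg = SimulationConfig(n_locations=10, rho=0.3, sigma_year=0.1, seed=4)
    path = tmp_path / "sim.yaml"
    cfg.to_file(path)
    back = SimulationConfig.from_file(path)
    assert back == cfg


def test_unknown_config_key_rejected(tmp_path):
    path = tmp_path / "sim.yaml"
    path.write_text("n_locations: 5\nwibble: 3\n")
    with pytest.raises(ConfigError, match="wibble"):
        SimulationConfig.from_file(path)
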