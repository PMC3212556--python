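"""Distributional laws, calibration and determinism of the season simulator."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest
from scipy import special

from vinebirds.io_types import write_pointcounts, write_sentinel
from vinebirds.synthetic_data import (
    SentinelConfig,
    SimConfig,
    SpeciesRates,
    default_species_pool,
    simulate_nests,
    simulate_pointcounts,
    simulate_sentinel,
)


def _focal_pool(rate, mult):
    return (SpeciesRates("WEBL", "I", rate, mult),)


class TestPointcountLaws:
    def test_focal_nestbox_mean_matches_poisson_rate(self):
        # rate 0.18 x multiplier 10 -> mean per-interval count about 1.8
        cfg = SimConfig(seed=5, n_sites=1, points_per_area=30, visits_per_period=20,
                        species_pool=_focal_pool(0.18, 10.0))
        frame = simulate_pointcounts(cfg)
        n_intervals = 30 * 60 * 6  # points x visits x intervals
        nb = frame[frame.area == "nestbox"]["count"].sum() / n_intervals
        ctrl = frame[frame.area == "control"]["count"].sum() / n_intervals
        assert nb == pytest.approx(1.8, abs=3 * np.sqrt(1.8 / n_intervals))
        assert ctrl == pytest.approx(0.18, abs=3 * np.sqrt(0.18 / n_intervals))

    def test_poisson_variance_matches_mean(self):
        cfg = SimConfig(seed=6, n_sites=1, points_per_area=30, visits_per_period=20,
                        species_pool=_focal_pool(0.5, 1.0))
        frame = simulate_pointcounts(cfg)
        n_cells = 2 * 30 * 60 * 6
        counts = np.zeros(n_cells)
        counts[: len(frame)] = frame["count"].to_numpy()
        assert counts.mean() == pytest.approx(0.5, rel=0.05)
        assert counts.var() == pytest.approx(0.5, rel=0.05)

    def test_unit_multiplier_is_symmetric_in_expectation(self):
        cfg = SimConfig(seed=7, species_pool=_focal_pool(0.5, 1.0))
        frame = simulate_pointcounts(cfg)
        by_area = frame.groupby("area")["count"].sum()
        n = by_area.sum()
        # two-proportion z-test style bound at ~4 sigma
        assert abs(by_area["nestbox"] - by_area["control"]) < 4 * np.sqrt(n)

    def test_distances_within_radius(self):
        frame = simulate_pointcounts(SimConfig(seed=8))
        assert frame["distance_m"].between(0, 85).all()

    def test_overdispersed_mode_inflates_variance(self):
        base = SimConfig(seed=9, n_sites=1, points_per_area=20, visits_per_period=10,
                         species_pool=_focal_pool(1.0, 1.0))
        od = dataclasses.replace(base, overdispersion=0.5)
        n_cells = 2 * 20 * 30 * 6
        var = {}
        for name, cfg in (("poisson", base), ("nb", od)):
            frame = simulate_pointcounts(cfg)
            counts = np.zeros(n_cells)
            counts[: len(frame)] = frame["count"].to_numpy()
            var[name] = counts.var()
        assert var["nb"] > 1.5 * var["poisson"]


class TestSentinelLaws:
    def test_probability_one_removes_everything(self):
        sc = SentinelConfig(beta_control=20.0, beta_nestbox=20.0, beta_active=20.0,
                            sigma_b=0.0)
        transects = simulate_sentinel(SimConfig(seed=1, sentinel=sc))
        assert all(t.removed == 5 for t in transects)

    def test_binomial_mean_at_half(self):
        sc = SentinelConfig(beta_control=0.0, beta_nestbox=0.0, beta_active=0.0,
                            sigma_b=0.0, control_per_site=200, nestbox_per_site=200,
                            active_per_site=(200,))
        transects = simulate_sentinel(SimConfig(seed=2, n_sites=2, sentinel=sc))
        removed = np.array([t.removed for t in transects])
        se = np.sqrt(5 * 0.5 * 0.5 / len(removed))
        assert removed.mean() == pytest.approx(2.5, abs=4 * se)

    def test_default_logits_encode_study_group_means(self):
        sc = SentinelConfig()
        for beta, mean in ((sc.beta_control, 1.2), (sc.beta_nestbox, 2.9),
                           (sc.beta_active, 4.14)):
            assert 5 * special.expit(beta) == pytest.approx(mean, abs=1e-9)

    def test_conditional_group_means_near_study_values(self):
        # with the block effect silenced the group means hit the calibrated values
        sc = SentinelConfig(sigma_b=0.0, control_per_site=300, nestbox_per_site=300,
                            active_per_site=(300,))
        transects = simulate_sentinel(SimConfig(seed=3, n_sites=2, sentinel=sc))
        df = pd.DataFrame({"g": [t.group for t in transects],
                           "r": [t.removed for t in transects]})
        means = df.groupby("g")["r"].mean()
        for group, target in (("control", 1.2), ("nestbox_random", 2.9),
                              ("active_nest", 4.14)):
            se = np.sqrt(target * (1 - target / 5) / 600)
            assert means[group] == pytest.approx(target, abs=4 * se)

    def test_paper_sized_design(self):
        transects = simulate_sentinel(SimConfig(seed=4))
        counts = pd.Series([t.group for t in transects]).value_counts()
        assert counts["control"] == 10
        assert counts["nestbox_random"] == 10
        assert counts["active_nest"] == 7
        blocks = {t.block for t in transects}
        assert len(blocks) == 4  # site x vineyard-half


class TestDeterminism:
    def test_pointcounts_byte_identical(self):
        cfg = SimConfig(seed=11)
        outs = []
        for _ in range(2):
            buf = io.StringIO()
            write_pointcounts(simulate_pointcounts(cfg), buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_sentinel_byte_identical(self):
        cfg = SimConfig(seed=11)
        outs = []
        for _ in range(2):
            buf = io.StringIO()
            write_sentinel(simulate_sentinel(cfg), buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_different_seeds_differ(self):
        a = simulate_pointcounts(SimConfig(seed=1))
        b = simulate_pointcounts(SimConfig(seed=2))
        assert not a.equals(b)


class TestConfig:
    def test_default_pool_covers_all_species(self):
        pool = default_species_pool()
        assert len(pool) == 25
        assert all(s.rate >= 0 and s.multiplier >= 0 for s in pool)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sites=0)
        with pytest.raises(ValueError):
            SentinelConfig(sigma_b=-1.0)
        with pytest.raises(ValueError):
            SpeciesRates("WEBL", "I", -0.1, 1.0)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "n_sites: 3\nvisits_per_period: 4\nseed: 17\n"
            "sentinel:\n  sigma_b: 0.25\n  active_per_site: [2, 3]\n"
        )
        cfg = SimConfig.from_yaml(path)
        assert cfg.n_sites == 3
        assert cfg.visits_per_period == 4
        assert cfg.seed == 17
        assert cfg.sentinel.sigma_b == 0.25
        assert cfg.sentinel.active_per_site == (2, 3)


def test_nest_records_clutch_law():
    records = simulate_nests(SimConfig(seed=12), box_pairs_per_site=400)
    clutches = np.array([r.clutch_size for r in records])
    assert set(np.unique(clutches)) <= {4, 5, 6}
    # occupancy ~76% of pairs, clutch mean ~4.91
    assert len(records) / 800 == pytest.approx(0.761, abs=0.06)
    assert clutches.mean() == pytest.approx(4.91, abs=0.1)
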