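"""Heritability estimation, community metrics, and cross-run models."""

import numpy as np
import pandas as pd
import pytest

from netcomm.engine import RunRecord, SimConfig, SpeciesParams
from netcomm.metrics_analysis import (
    coexistence,
    critical_population,
    fit_summary_models,
    metapop_contrast,
    metrics_09k_table,
    midparent_heritability,
    mismatch,
    persistence_time,
    prop_above_09k,
    time_to_09k,
)


class TestHeritability:
    def test_identity_mapping_gives_unit_slope(self):
        x = np.linspace(10, 90, 50)
        assert midparent_heritability(x, x) == pytest.approx(1.0)

    def test_independent_offspring_give_null_slope(self, rng):
        mid = rng.normal(70, 10, 10_000)
        off = rng.normal(70, 10, 10_000)
        assert abs(midparent_heritability(off, mid)) < 0.03

    def test_planted_heritability_recovered(self, rng):
        h2, n = 0.5, 5_000
        mid = rng.normal(70, 10, n)
        off = 70 + h2 * (mid - 70) + rng.normal(0, 10 * np.sqrt(1 - h2**2 / 4), n)
        assert midparent_heritability(off, mid) == pytest.approx(h2, abs=0.05)

    def test_degenerate_inputs_return_nan(self):
        assert np.isnan(midparent_heritability([1.0, 2.0], [1.0, 2.0]))
        assert np.isnan(midparent_heritability([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))

    def test_slope_invariant_under_shared_affine_transform(self, rng):
        mid = rng.normal(70, 10, 500)
        off = 0.4 * mid + rng.normal(0, 5, 500)
        base = midparent_heritability(off, mid)
        scaled = midparent_heritability(3.0 * off - 12.0, 3.0 * mid - 12.0)
        assert scaled == pytest.approx(base)


def _fake_run(census_by_gen, generations=None, horizon=20):
    """Minimal RunRecord with a single species carrying the given censuses."""
    gens = np.arange(len(census_by_gen))
    census = np.asarray(census_by_gen)
    tab = pd.DataFrame({"generation": gens})
    for p in range(3):
        tab[f"resource_q_p{p}"] = 70.0
        # everything lives in patch 0, split between the two species
        tab[f"census_focal_p{p}"] = census // 2 if p == 0 else 0
        tab[f"mean_phen_focal_p{p}"] = 70.0
        tab[f"census_competitor_p{p}"] = census - census // 2 if p == 0 else 0
        tab[f"mean_phen_competitor_p{p}"] = 70.0
    cfg = SimConfig(generations=horizon, canalization_gens=2)
    return RunRecord(
        table=tab,
        species=["focal", "competitor"],
        extinction_gen={"focal": None, "competitor": None},
        coexistence=True,
        generations_run=generations if generations is not None else len(census_by_gen) - 1,
        config=cfg,
        params=[
            SpeciesParams(name="focal", start_patch=0),
            SpeciesParams(name="competitor", start_patch=1),
        ],
        seed=0,
    )


class TestCommunityMetrics:
    def test_persistence_capped_at_horizon(self):
        run = _fake_run([100] * 21, horizon=20)
        assert persistence_time(run) == 20
        run.extinction_gen["competitor"] = 12
        assert persistence_time(run) == 12

    def test_coexistence_requires_surviving_to_horizon(self):
        run = _fake_run([100] * 21, generations=20, horizon=20)
        assert coexistence(run)
        early = _fake_run([100] * 13, generations=12, horizon=20)
        assert not coexistence(early)

    def test_critical_population_is_90_percent_of_peak(self):
        runs = [_fake_run([30, 600, 300]), _fake_run([30, 50, 40])]
        assert critical_population(runs) == pytest.approx(540.0)

    def test_time_to_and_prop_above_threshold(self):
        census = [0] * 10 + [600] * 11  # pinned at 600 from generation 10
        run = _fake_run(census, horizon=20)
        assert time_to_09k(run, 540.0) == 10
        assert prop_above_09k(run, 540.0) == pytest.approx(11 / 21)

    def test_never_reaching_threshold(self):
        run = _fake_run([100] * 21, horizon=20)
        assert np.isnan(time_to_09k(run, 540.0))
        assert prop_above_09k(run, 540.0) == 0.0

    def test_metapop_contrast_centers_identical_arms_on_zero(self):
        runs = [_fake_run([0] * 5 + [600] * 16, horizon=20) for _ in range(3)]
        tab = metrics_09k_table(runs, ["L1", "L1", "L1"], 540.0)
        out = metapop_contrast(tab, tab)
        assert np.allclose(out["delta_time_to_09k"], 0.0)
        assert np.allclose(out["delta_prop_above_09k"], 0.0)
        assert len(out) == 3

    def test_metapop_contrast_rejects_unmatched_landscape(self):
        runs = [_fake_run([600] * 21)]
        a = metrics_09k_table(runs, ["L1"], 540.0)
        b = metrics_09k_table(runs, ["L2"], 540.0)
        with pytest.raises(ValueError):
            metapop_contrast(a, b)


class TestMismatch:
    def test_perfectly_adapted_population_has_zero_mismatch(self):
        assert mismatch(_fake_run([300] * 21)) == 0.0

    def test_single_occupied_patch_gives_plain_gap(self):
        run = _fake_run([300] * 21)
        for p in (1, 2):
            for s in ("focal", "competitor"):
                run.table[f"census_{s}_p{p}"] = 0
        run.table["mean_phen_focal_p0"] = 75.0
        run.table["mean_phen_competitor_p0"] = 75.0
        assert mismatch(run) == pytest.approx(5.0)

    def test_empty_world_is_nan(self):
        run = _fake_run([0] * 21)
        assert np.isnan(mismatch(run))


class TestSummaryModels:
    @staticmethod
    def _summary(rng, effect="d"):
        rows = []
        for d in (0.01, 0.05, 0.1):
            for n in (16, 64, 256):
                for mu in (1e-3, 1e-4, 1e-5):
                    for rep in range(3):
                        persist = 700 - (4000 * d if effect == "d" else n) + rng.normal(0, 10)
                        rows.append(
                            dict(
                                competitor_d=d,
                                competitor_n=n,
                                competitor_mu=mu,
                                heterogeneity=rng.integers(1, 4),
                                coexistence=bool(rng.random() < 0.3 + (2 - 20 * d)) if d else 0,
                                persistence=persist,
                            )
                        )
        return pd.DataFrame(rows)

    def test_planted_dispersal_effect_dominates(self, rng):
        report = fit_summary_models(self._summary(rng, effect="d"))
        tab = report.persistence_table.set_index("factor")
        assert tab.loc["competitor_d", "pct_var"] > 10 * tab.loc["competitor_n", "pct_var"]
        assert tab.loc["competitor_d", "pct_var"] > 10 * tab.loc["competitor_mu", "pct_var"]

    def test_null_data_explains_nearly_nothing(self, rng):
        df = self._summary(rng)
        df["persistence"] = rng.normal(400, 50, len(df))
        report = fit_summary_models(df)
        tab = report.persistence_table.set_index("factor")
        assert tab.loc["competitor_d", "pct_var"] < 5

    def test_report_layout_one_row_per_factor_plus_residual(self, rng):
        report = fit_summary_models(self._summary(rng))
        assert list(report.coexistence_table["factor"]) == [
            "competitor_d",
            "competitor_n",
            "heterogeneity",
            "residual",
        ]
        assert list(report.persistence_table["factor"]) == [
            "competitor_d",
            "competitor_n",
            "competitor_mu",
            "residual",
        ]

    def test_single_level_factor_dropped_with_warning(self, rng):
        df = self._summary(rng)
        df["competitor_n"] = 16
        report = fit_summary_models(df)
        assert any("competitor_n" in w for w in report.warnings)
        assert "competitor_n" not in list(report.persistence_table["factor"])
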