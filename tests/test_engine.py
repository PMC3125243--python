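"""Scheduler ordering, run determinism, and the experiment driver."""

import numpy as np
import pandas as pd
import pytest

from netcomm.engine import (
    DEFAULT_METAPOP_LANDSCAPES,
    SimConfig,
    SpeciesParams,
    enumerate_design,
    initialize_run,
    run_experiment,
    run_metapopulation_arm,
    run_seed,
    run_simulation,
)


def short_config(**kw):
    defaults = dict(generations=30, canalization_gens=5)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture
def species_pair():
    return (
        SpeciesParams(name="focal", start_patch=0, d=0.05),
        SpeciesParams(name="competitor", start_patch=1, d=0.05),
    )


class TestInitialization:
    def test_founding_censuses(self, species_pair, rng):
        world = initialize_run(SimConfig(), *species_pair, rng)
        row = world.rows[0]
        assert row["census_focal_p0"] == 100
        assert row["census_competitor_p1"] == 100
        assert row["census_focal_p1"] == row["census_competitor_p0"] == 0
        assert row["census_focal_p2"] == row["census_competitor_p2"] == 0
        assert all(row[f"resource_q_p{p}"] == 70.0 for p in range(3))

    def test_founders_are_genetically_distinct(self, species_pair, rng):
        world = initialize_run(SimConfig(), *species_pair, rng)
        pop = world.pops[0]
        rows = {tuple(pop.heads[i]) + tuple(pop.funcs[i]) for i in range(pop.size)}
        assert len(rows) > 95  # random networks are essentially never duplicated

    def test_shared_start_patch_rejected(self, rng):
        a = SpeciesParams(name="a", start_patch=0)
        b = SpeciesParams(name="b", start_patch=0)
        with pytest.raises(ValueError):
            initialize_run(SimConfig(), a, b, rng)


class TestRunSimulation:
    def test_same_seed_is_bit_identical(self, species_pair):
        cfg = short_config()
        r1 = run_simulation(cfg, *species_pair, seed=7)
        r2 = run_simulation(cfg, *species_pair, seed=7)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.extinction_gen == r2.extinction_gen

    def test_different_seeds_differ(self, species_pair):
        cfg = short_config()
        r1 = run_simulation(cfg, *species_pair, seed=1)
        r2 = run_simulation(cfg, *species_pair, seed=2)
        assert not r1.table.equals(r2.table)

    def test_no_dispersal_during_canalization(self, species_pair):
        cfg = SimConfig(generations=40, canalization_gens=20)
        foc = SpeciesParams(name="focal", start_patch=0, d=0.5)
        comp = SpeciesParams(name="competitor", start_patch=1, d=0.5)
        rec = run_simulation(cfg, foc, comp, seed=3)
        tab = rec.table
        early = tab[(tab.generation >= 1) & (tab.generation <= 20)]
        assert (early[["migrants_focal", "migrants_competitor"]].to_numpy() == 0).all()
        late = tab[tab.generation > 20]
        assert late[["migrants_focal", "migrants_competitor"]].to_numpy().sum() > 0

    def test_carrying_capacity_bounds_every_generation(self, species_pair):
        rec = run_simulation(short_config(), *species_pair, seed=11)
        tab = rec.table
        for p in range(3):
            joint = tab[f"census_focal_p{p}"] + tab[f"census_competitor_p{p}"]
            assert (joint <= 200).all()
        assert (rec.total_regional_census() <= 600).all()

    def test_extinction_is_absorbing_and_stops_the_run(self):
        # a large-network competitor fails to establish under default selection
        cfg = SimConfig(generations=200)
        foc = SpeciesParams(name="focal", start_patch=0, d=0.05)
        comp = SpeciesParams(name="competitor", start_patch=1, d=0.05, n=256)
        rec = run_simulation(cfg, foc, comp, seed=5)
        gone = [s for s, g in rec.extinction_gen.items() if g is not None]
        assert gone, "expected at least one extinction in this configuration"
        assert rec.generations_run == min(
            g for g in rec.extinction_gen.values() if g is not None
        )
        name = gone[0]
        last = rec.table.iloc[-1]
        assert sum(last[f"census_{name}_p{p}"] for p in range(3)) == 0
        assert not rec.coexistence

    def test_metapopulation_degenerate_config_runs_to_horizon(self):
        cfg = short_config()
        foc = SpeciesParams(name="focal", start_patch=0, d=0.05)
        absent = SpeciesParams(name="competitor", start_patch=1, n0=0)
        rec = run_simulation(cfg, foc, absent, seed=2)
        assert rec.generations_run == cfg.generations
        assert not rec.coexistence  # a lone species cannot coexist
        assert (rec.regional_census("competitor") == 0).all()


class TestExperimentDriver:
    def test_single_cell_single_replicate(self):
        cfg = short_config()
        summary, records = run_experiment(
            {"competitor_d": [0.05]}, replicates=1, master_seed=1, config=cfg,
            keep_records=True,
        )
        assert len(summary) == 1 and len(records) == 1
        assert {"coexistence", "persistence", "mismatch", "heterogeneity"} <= set(
            summary.columns
        )

    def test_design_enumeration_is_full_factorial(self):
        cells = enumerate_design({"a": [1, 2], "b": ["x", "y", "z"]})
        assert len(cells) == 6

    def test_summary_row_count_and_reproducibility(self):
        cfg = short_config()
        design = {"competitor_n": [16, 64], "competitor_d": [0.01, 0.1]}
        s1, _ = run_experiment(design, replicates=2, master_seed=9, config=cfg)
        s2, _ = run_experiment(design, replicates=2, master_seed=9, config=cfg)
        assert len(s1) == 8
        pd.testing.assert_frame_equal(s1, s2)

    def test_per_run_seeds_are_stable_and_bounded(self):
        s = run_seed(123, 4, 2)
        assert s == run_seed(123, 4, 2)
        assert 0 <= s < 2**31
        assert s != run_seed(123, 4, 3)

    def test_metapopulation_arm_dimensions(self):
        cfg = short_config()
        summary, _ = run_metapopulation_arm(
            landscapes=DEFAULT_METAPOP_LANDSCAPES[:2],
            replicates=2,
            master_seed=4,
            config=cfg,
        )
        assert len(summary) == 4
        assert summary["landscape"].nunique() == 2

    def test_default_metapop_landscape_set(self):
        assert len(DEFAULT_METAPOP_LANDSCAPES) == 7
        hets = sorted(len(set(r)) for r in DEFAULT_METAPOP_LANDSCAPES)
        assert hets == [1, 1, 1, 2, 2, 2, 3]
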