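"""Individual-based population engine and the four life-history archetypes."""

import numpy as np
import pytest
from scipy import stats

import mosaicpop as mp


class TestArchetypes:
    def test_ordinal_life_history_relations(self):
        a = {n: mp.make_archetype(n) for n in mp.ARCHETYPE_NAMES}
        # short dispersers vs fliers
        assert a["beetle"].d_max < a["skylark"].d_max
        assert a["vole"].d_max < a["spider"].d_max
        # ballooning is costly
        assert a["spider"].dispersal_mortality > a["beetle"].dispersal_mortality
        # fast vs slow life histories
        assert a["beetle"].r_max > a["vole"].r_max
        assert a["spider"].r_max > a["skylark"].r_max

    def test_mechanism_flags(self):
        a = {n: mp.make_archetype(n) for n in mp.ARCHETYPE_NAMES}
        assert a["beetle"].complementation_types  # overwintering boundaries
        assert a["beetle"].barriers_block and a["vole"].barriers_block
        assert not a["skylark"].barriers_block and not a["spider"].barriers_block
        assert "forest" in a["skylark"].avoidance_types  # tree avoidance
        assert a["vole"].fecundity_multiplier["grassland"] == max(
            a["vole"].fecundity_multiplier.values()
        )

    def test_unknown_archetype_lists_valid_names(self):
        with pytest.raises(KeyError, match="beetle"):
            mp.make_archetype("aurochs")


class TestInitPopulation:
    def test_zero_density_empty(self, grass_landscape):
        pop = mp.init_population(grass_landscape, mp.make_archetype("vole"), 0.0, seed=0)
        assert len(pop) == 0

    def test_rounding_to_nearest(self):
        ls = mp.landscape_from_arrays(np.ones((10, 10), int), {1: "rotational_field"})
        pop = mp.init_population(ls, mp.make_archetype("beetle"), 0.1, seed=0)
        assert len(pop) == 10

    def test_placement_uniform_over_habitable_cells(self, grass_landscape):
        sp = mp.make_archetype("vole")
        counts = np.zeros(900)
        for seed in range(300):
            pop = mp.init_population(grass_landscape, sp, 30 / 900, seed=seed)
            np.add.at(counts, pop.rows.astype(int) * 30 + pop.cols, 1)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, df=counts.size - 1)
        assert p > 0.01

    def test_no_habitable_cell_raises(self):
        ls = mp.landscape_from_arrays(np.ones((5, 5), int), {1: "forest"})
        with pytest.raises(ValueError, match="habitable"):
            mp.init_population(ls, mp.make_archetype("beetle"), 0.1, seed=0)


class TestStepYear:
    def test_zero_survival_empties_population(self, grass_landscape):
        sp = mp.make_archetype("vole").with_overrides(
            overwinter_survival={t: 0.0 for t in mp.HABITAT_TYPES}
        )
        pop = mp.init_population(grass_landscape, mp.make_archetype("vole"), 0.2, seed=1)
        out = mp.step_year(pop, grass_landscape, sp, 1.0, seed=2)
        assert len(out) == 0

    def test_empty_in_empty_out(self, grass_landscape):
        out = mp.step_year(
            mp.ibm.Population.empty(), grass_landscape, mp.make_archetype("vole"), 1.0, seed=0
        )
        assert len(out) == 0

    def test_low_density_growth_factor(self):
        """With survival 1, no dispersal mortality and n << kappa*area the
        expected yearly growth factor is 1 + r_max * fecundity * w_y."""
        ls = mp.landscape_from_arrays(np.ones((50, 50), int), {1: "grassland"})
        sp = mp.make_archetype("vole").with_overrides(
            overwinter_survival={t: 1.0 for t in mp.HABITAT_TYPES},
            dispersal_mortality=0.0,
        )
        w = 1.2
        n0, reps, totals = 100, 60, []
        ctx = mp.SimulationContext(ls, sp)
        for r in range(reps):
            pop = mp.init_population(ls, sp, n0 / 2500, seed=r, ctx=ctx)
            out = mp.step_year(pop, ls, sp, w, seed=1000 + r, ctx=ctx)
            totals.append(len(out))
        expected = n0 * (1 + sp.r_max * 1.0 * w * (1 - n0 / (3.0 * 2500)))
        se = np.std(totals) / np.sqrt(reps)
        assert abs(np.mean(totals) - expected) < 3 * se + 0.01 * expected

    def test_census_is_total_and_matches_per_patch_sum(self, grass_landscape):
        pop = mp.init_population(grass_landscape, mp.make_archetype("vole"), 0.3, seed=3)
        assert mp.census(pop) == len(pop.rows)
        pid = grass_landscape.grid[pop.rows, pop.cols]
        assert np.bincount(pid).sum() == mp.census(pop)

    def test_no_individual_on_barrier_after_steps(self, margin_landscape):
        for name in ("beetle", "spider"):
            sp = mp.make_archetype(name)
            ctx = mp.SimulationContext(margin_landscape, sp)
            pop = mp.init_population(margin_landscape, sp, 0.3, seed=4, ctx=ctx)
            bm = margin_landscape.barrier_mask()
            for yr in range(5):
                assert not bm[pop.rows, pop.cols].any()
                pop = mp.step_year(pop, margin_landscape, sp, 1.0, seed=yr, ctx=ctx)
            assert not bm[pop.rows, pop.cols].any()

    def test_single_patch_equilibrium_matches_deterministic_fixed_point(self, grass_landscape):
        """Closed iteroparous population fluctuates around the fixed point of
        the matched deterministic map N' = sN(1 + r f (1 - N/C))."""
        sp = mp.make_archetype("vole")
        s = sp.overwinter_survival["grassland"]
        eff_r = sp.r_max * (1 - sp.dispersal_mortality)
        C = sp.capacity_density["grassland"] * 900
        n_star = C * (1 - (1 - s) / (s * eff_r))
        ctx = mp.SimulationContext(grass_landscape, sp)
        pop = mp.init_population(grass_landscape, sp, 1.0, seed=5, ctx=ctx)
        series = []
        for yr in range(60):
            pop = mp.step_year(pop, grass_landscape, sp, 1.0, seed=yr, ctx=ctx)
            if yr >= 20:
                series.append(len(pop))
        assert abs(np.mean(series) - n_star) / n_star < 0.10


class TestComplementation:
    def test_equilibrium_drops_when_overwinter_habitat_displaced(self, strip_landscape_factory):
        """Beetle abundance collapses when all boundary habitat lies beyond
        the complementation radius of the field (landscape
        complementation mechanism)."""
        sp = mp.make_archetype("beetle")
        means = {}
        for label, gap in (("near", 0), ("far", sp.complementation_radius + 3)):
            ls = strip_landscape_factory(gap)
            ctx = mp.SimulationContext(ls, sp)
            pop = mp.init_population(ls, sp, 0.5, seed=6, ctx=ctx)
            series = []
            for yr in range(40):
                pop = mp.step_year(pop, ls, sp, 1.0, seed=yr, ctx=ctx)
                if yr >= 15:
                    series.append(len(pop))
            means[label] = np.mean(series)
        assert means["far"] < 0.5 * means["near"]
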