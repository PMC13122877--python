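"""Tests of the synthetic-trial generators against design contracts and
Monte-Carlo oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pinedrought.containers import GeneticArchitecture
from pinedrought.simulate import (
    GrowthParams,
    InfeasibleDesignError,
    simulate_breeding_values,
    simulate_climate,
    simulate_genotypes,
    simulate_pedigree,
    simulate_ring_series,
    substream,
)


class TestPedigree:
    def test_smallest_diallel_gives_two_founders_and_three_sibs(self):
        ped = simulate_pedigree(2, 1, (3, 3), (1, 1), seed=0)
        assert len(ped.founders) == 2
        assert len(ped.progeny) == 3
        sires = {s for s, g in zip(ped.sire, ped.generation) if g > 0}
        dams = {d for d, g in zip(ped.dam, ped.generation) if g > 0}
        assert len(sires) == 1 and len(dams) == 1

    def test_complete_half_diallel_usage_counts(self):
        """4 parents x 6 families must enumerate all C(4,2) pairs, each
        parent appearing in exactly 3 crosses (brute-force enumeration)."""
        ped = simulate_pedigree(4, 6, (1, 1), (3, 3), seed=1)
        fams = ped.families()
        all_pairs = {
            tuple(sorted(p)) for p in itertools.combinations(ped.founders, 2)
        }
        assert set(fams.keys()) == all_pairs
        usage = {p: 0 for p in ped.founders}
        for a, b in fams:
            usage[a] += 1
            usage[b] += 1
        assert all(v == 3 for v in usage.values())

    def test_study_scale_design(self):
        """33 parents / 158 families with sizes 1-7: distinct families,
        progeny total near the study's scale."""
        ped = simulate_pedigree(33, 158, (1, 7), (8, 9), seed=2)
        assert len(ped.founders) == 33
        fams = ped.families()
        assert len(fams) == 158
        sizes = [len(m) for m in fams.values()]
        assert min(sizes) >= 1 and max(sizes) <= 7
        # uniform sizes on 1..7 give expectation 632; the study had 559
        assert 450 <= len(ped.progeny) <= 800

    def test_too_many_families_is_infeasible(self):
        with pytest.raises(InfeasibleDesignError, match="distinct parent"):
            simulate_pedigree(4, 7, (1, 1), (1, 10), seed=0)

    def test_pedigree_is_topologically_ordered(self):
        ped = simulate_pedigree(10, 15, (2, 4), (1, 8), seed=3)
        pos = {i: k for k, i in enumerate(ped.ids)}
        for i, s, d, g in zip(ped.ids, ped.sire, ped.dam, ped.generation):
            if g > 0:
                assert pos[s] < pos[i] and pos[d] < pos[i]


class TestGenotypes:
    def test_forced_heterozygosity_of_f1(self, trio_pedigree):
        """AA x aa founders make every offspring dosage exactly 1."""
        geno = simulate_genotypes(trio_pedigree, 50, (0.4999, 0.5), 0.0, seed=0)
        X = geno.dosages
        fixed = (X[0] == 2) & (X[1] == 0) | (X[0] == 0) & (X[1] == 2)
        assert fixed.any()
        assert np.all(X[2:, fixed] == 1)

    def test_missing_rate_and_shape(self):
        ped = simulate_pedigree(6, 8, (3, 3), (1, 6), seed=1)
        geno = simulate_genotypes(ped, 400, (0.05, 0.5), 0.1, seed=2)
        assert geno.dosages.shape == (len(ped), 400)
        assert abs(np.isnan(geno.dosages).mean() - 0.1) < 0.02

    def test_fullsib_identity_correlation_half(self):
        """Centred-dosage covariance of full sibs approximates half the
        dosage variance (gene-dropping expectation, Monte-Carlo)."""
        ped = simulate_pedigree(2, 1, (2, 2), (1, 1), seed=3)
        # pin the founder allele frequency at 0.5 so centring is exact
        geno = simulate_genotypes(ped, 10_000, (0.4999, 0.5), 0.0, seed=4)
        Z = geno.dosages - 1.0
        denom = np.mean([Z[2] @ Z[2], Z[3] @ Z[3]])
        rel = (Z[2] @ Z[3]) / denom
        assert rel == pytest.approx(0.5, abs=0.05)

    def test_unknown_parent_progeny_rejected(self):
        from pinedrought.containers import Pedigree

        bad = Pedigree(
            ids=["A", "B", "C"], sire=["0", "0", "A"], dam=["0", "0", "0"],
            generation=[0, 0, 1],
        )
        with pytest.raises(ValueError, match="unknown parents"):
            simulate_genotypes(bad, 10, (0.1, 0.5), 0.0, seed=0)


class TestBreedingValues:
    def test_zero_genetic_covariance_gives_zero_bvs(self, trio_pedigree):
        geno = simulate_genotypes(trio_pedigree, 100, (0.1, 0.5), 0.0, seed=0)
        arch = GeneticArchitecture(["a", "b"], np.zeros((2, 2)), np.eye(2), 20)
        tv = simulate_breeding_values(geno, arch, seed=1)
        assert np.all(tv.breeding_values == 0.0)

    def test_perfect_genetic_correlation_duplicates_traits(self, trio_pedigree):
        geno = simulate_genotypes(trio_pedigree, 200, (0.1, 0.5), 0.0, seed=2)
        arch = GeneticArchitecture.from_targets(
            ["a", "b"], [0.5, 0.5], genetic_corr=1.0, n_causal=50
        )
        tv = simulate_breeding_values(geno, arch, seed=3)
        bv = tv.breeding_values
        np.testing.assert_allclose(
            bv[:, 0] - bv[:, 0].mean(), bv[:, 1] - bv[:, 1].mean(), atol=1e-8
        )

    def test_realized_covariance_matches_sigma_a_exactly(self):
        ped = simulate_pedigree(10, 20, (4, 4), (2, 6), seed=4)
        geno = simulate_genotypes(ped, 1000, (0.05, 0.5), 0.05, seed=5)
        arch = GeneticArchitecture.from_targets(
            ["a", "b"], [0.4, 0.6], genetic_corr=0.7, n_causal=200
        )
        tv = simulate_breeding_values(geno, arch, seed=6)
        C = np.cov(tv.breeding_values, rowvar=False)
        np.testing.assert_allclose(C, arch.Sigma_a, atol=1e-10)

    def test_target_genetic_correlation_recovered_across_seeds(self):
        """Sample correlation of true BVs tracks the target 0.7."""
        ped = simulate_pedigree(20, 60, (5, 5), (4, 8), seed=7)
        geno = simulate_genotypes(ped, 1500, (0.05, 0.5), 0.0, seed=8)
        arch = GeneticArchitecture.from_targets(
            ["a", "b"], [0.5, 0.5], genetic_corr=0.7, n_causal=500
        )
        corrs = []
        for s in range(10):
            tv = simulate_breeding_values(geno, arch, seed=100 + s)
            corrs.append(np.corrcoef(tv.breeding_values.T)[0, 1])
        assert np.mean(corrs) == pytest.approx(0.7, abs=0.05)

    def test_breeding_value_equals_dosage_times_effects(self, trio_pedigree):
        geno = simulate_genotypes(trio_pedigree, 100, (0.1, 0.5), 0.0, seed=9)
        arch = GeneticArchitecture.from_targets(["a"], [0.5], n_causal=30)
        tv = simulate_breeding_values(geno, arch, seed=10)
        np.testing.assert_allclose(
            tv.breeding_values, geno.dosages @ tv.causal_effects, atol=1e-10
        )


class TestRingSeries:
    @staticmethod
    def _truth(n_trees=40, seed=0):
        ped = simulate_pedigree(8, 10, (4, 4), (1, 6), seed=seed)
        geno = simulate_genotypes(ped, 300, (0.1, 0.5), 0.0, seed=seed + 1)
        arch = GeneticArchitecture.from_targets(
            ["growth", "resistance"], [0.3, 0.3], n_causal=100
        )
        return ped, simulate_breeding_values(geno, arch, seed=seed + 2)

    def test_deterministic_age_trend_without_noise_or_climate(self):
        ped, tv = self._truth()
        clim = simulate_climate(1971, 2011, seed=3)
        params = GrowthParams(
            phi=0.0, climate_sens=0.0, noise_sd=0.0, tree_env_sd=0.0,
            growth_sens=0.0, drought_mult=1.0, resistance_slope=0.0,
            recovery_slope=0.0,
        )
        rings, _ = simulate_ring_series(tv, clim, params, seed=4,
                                        tree_ids=ped.progeny[:5])
        one = rings[rings["tree"] == ped.progeny[0]].sort_values("year")
        ages = one["year"].to_numpy() - params.planting_year
        np.testing.assert_allclose(
            one["RW"].to_numpy(), params.age_trend(ages), rtol=1e-12
        )

    def test_drought_years_outside_climate_span_error(self):
        ped, tv = self._truth()
        clim = simulate_climate(1971, 2000, seed=3)
        params = GrowthParams(last_year=2000, drought_years=(2002, 2003))
        with pytest.raises(ValueError, match="drought year"):
            simulate_ring_series(tv, clim, params, seed=4, tree_ids=ped.progeny)

    def test_resistance_bv_raises_drought_ring_width(self):
        """Positive resistance slope: higher resistance BV, higher realized
        drought-year growth relative to the individual's own level."""
        signs = []
        for s in range(10):
            ped, tv = self._truth(seed=20 + 3 * s)
            clim = simulate_climate(1971, 2011, seed=50 + s)
            params = GrowthParams(
                resistance_slope=0.6, noise_sd=0.05, drought_mult=0.6
            )
            rings, _ = simulate_ring_series(
                tv, clim, params, seed=60 + s, tree_ids=ped.progeny
            )
            dr = rings[rings["year"].isin(params.drought_years)]
            pre = rings[rings["year"].isin([1999, 2000, 2001])]
            ratio = (
                dr.groupby("tree")["RW"].mean() / pre.groupby("tree")["RW"].mean()
            )
            z = tv.bv("resistance").loc[ratio.index]
            signs.append(np.corrcoef(ratio, z)[0, 1])
        assert np.mean(signs) > 0.2

    def test_static_traits_hit_target_heritability(self):
        """var(BV-part)/var(phenotype) of HGT approximates static_h2."""
        ped = simulate_pedigree(20, 60, (5, 5), (4, 8), seed=30)
        geno = simulate_genotypes(ped, 800, (0.05, 0.5), 0.0, seed=31)
        arch = GeneticArchitecture.from_targets(
            ["growth", "resistance"], [0.3, 0.3], n_causal=200
        )
        tv = simulate_breeding_values(geno, arch, seed=32)
        clim = simulate_climate(1971, 2011, seed=33)
        params = GrowthParams(static_h2=0.4)
        h2s = []
        for s in range(20):
            _, statics = simulate_ring_series(
                tv, clim, params, seed=100 + s, tree_ids=ped.progeny
            )
            z = tv.bv("growth").loc[statics["tree"]]
            z = (z - z.mean()) / z.std()
            gen = z * 1.2 * np.sqrt(0.4 / 0.6)
            h2s.append(gen.var() / statics["HGT"].var())
        assert np.mean(h2s) == pytest.approx(0.4, abs=0.05)


class TestReproducibility:
    def test_generators_bit_reproducible_under_master_seed(self):
        master = 42
        a = simulate_pedigree(6, 8, (2, 3), (1, 6),
                              seed=substream(master, "pedigree"))
        b = simulate_pedigree(6, 8, (2, 3), (1, 6),
                              seed=substream(master, "pedigree"))
        assert a.ids == b.ids and a.sire == b.sire and a.dam == b.dam
        ga = simulate_genotypes(a, 200, (0.1, 0.5), 0.1,
                                seed=substream(master, "geno"))
        gb = simulate_genotypes(b, 200, (0.1, 0.5), 0.1,
                                seed=substream(master, "geno"))
        np.testing.assert_array_equal(
            np.nan_to_num(ga.dosages, nan=-1), np.nan_to_num(gb.dosages, nan=-1)
        )

    def test_substreams_differ_between_names(self):
        assert substream(1, "pedigree") != substream(1, "genotypes")
        assert substream(1, "pedigree") != substream(2, "pedigree")


def test_climate_generator_covers_span_and_droughts():
    clim = simulate_climate(1990, 2011, seed=0, drought_years=(2002, 2003))
    assert clim["year"].min() == 1990 and clim["year"].max() == 2011
    assert len(clim) == 22 * 12
    assert (clim["precip"] >= 0).all()
    summer = clim[clim["month"].between(6, 8)].groupby("year")["precip"].sum()
    drought = summer.loc[[2002, 2003]].mean()
    normal = summer.drop([2002, 2003]).mean()
    assert drought < 0.6 * normal
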