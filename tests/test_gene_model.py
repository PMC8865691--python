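"""Geometry construction, GC heterogeneity and defect annotation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddtasep import gene_model as gm


class TestBuildUniformGene:
    def test_reference_gene(self):
        geom = gm.build_uniform_gene(20_000, 1, 3)
        assert geom.n_sites == 400
        assert geom.n_units == 100

    def test_single_unit(self):
        geom = gm.build_uniform_gene(200, 1, 3)
        assert (geom.n_sites, geom.n_units) == (4, 1)

    def test_wider_linkers(self):
        geom = gm.build_uniform_gene(2_000, 2, 3)
        assert (geom.n_sites, geom.n_units) == (40, 8)

    def test_non_divisible_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            gm.build_uniform_gene(20_050, 1, 3)

    def test_flattened_units_tile_the_lattice(self):
        geom = gm.build_uniform_gene(20_000)
        flat = [s for u in geom.units for s in (*u.linker_sites, *u.nuc_sites)]
        assert flat == list(range(1, 401))
        assert geom.units[0].linker_sites == (1,)  # the TSS is a linker

    @given(
        n_units=st.integers(1, 50),
        k_L=st.integers(1, 4),
        k_N=st.integers(1, 5),
    )
    def test_unit_structure_invariants(self, n_units, k_L, k_N):
        length = 50 * n_units * (k_L + k_N)
        geom = gm.build_uniform_gene(length, k_L, k_N)
        assert geom.n_sites == n_units * (k_L + k_N)
        nuc = geom.nuc_unit_of_site()
        # every site belongs to exactly one unit; linkers precede nuc sites
        for m, u in enumerate(geom.units):
            assert len(u.linker_sites) == k_L
            assert len(u.nuc_sites) == k_N
            assert u.nuc_sites[0] == u.linker_sites[-1] + 1
            assert all(nuc[s - 1] == m for s in u.nuc_sites)
            assert all(nuc[s - 1] == -1 for s in u.linker_sites)


class TestRates:
    def test_uniform_broadcast(self, gene_20kbp):
        p = gm.uniform_rates(gene_20kbp, 0.05, 1.0, 1.0, 0.1, 0.001)
        assert np.all(p.q_site == 1.0) and p.q_site.shape == (400,)
        assert np.all(p.h_c_m == 0.1) and p.h_c_m.shape == (100,)
        assert np.all(p.h_o_m == 0.001)

    def test_negative_rate_rejected(self, gene_20kbp):
        with pytest.raises(ValueError):
            gm.uniform_rates(gene_20kbp, -0.1, 1.0)

    def test_gc_advance_rate_bounds_and_mean(self):
        geom = gm.build_uniform_gene(50 * 4 * 2500)  # 10^4 sites
        q_i = gm.sample_gc_advance_rates(geom, q=1.0, seed=5)
        assert np.all((q_i >= 0.5) & (q_i <= 1.5))
        # sd per site = |1.5-0.5| * sqrt(50*.25)/50 = sqrt(12.5)/50
        se = np.sqrt(12.5) / 50 / np.sqrt(geom.n_sites)
        assert abs(q_i.mean() - 1.0) < 3 * se

    def test_gc_extreme_compositions(self):
        # all-GC gives the slow bound 0.5q, no-GC the fast bound 1.5q
        assert 1.0 * (0.5 * 50 + 1.5 * 0) / 50 == 0.5
        geom = gm.build_uniform_gene(400)
        q_i = gm.sample_gc_advance_rates(geom, q=2.0, seed=0)
        assert np.all((q_i >= 1.0) & (q_i <= 3.0))

    def test_gc_nucleosome_rates_shared_draw_and_mean(self):
        geom = gm.build_uniform_gene(50 * 4 * 2500)
        h_c_m, h_o_m = gm.sample_gc_nucleosome_rates(geom, 0.1, 0.01, seed=6)
        assert np.all((h_c_m >= 0.075) & (h_c_m <= 0.125))
        assert np.all((h_o_m >= 0.0075) & (h_o_m <= 0.0125))
        # one shared N_GC draw: deviations are exactly anti-symmetric
        dev_c = h_c_m / 0.1 - 1.0
        dev_o = h_o_m / 0.01 - 1.0
        np.testing.assert_allclose(dev_c, -dev_o, atol=1e-12)
        se = 0.5 * np.sqrt(150 * 0.25) / 150 / np.sqrt(geom.n_units)
        assert abs(h_c_m.mean() / 0.1 - 1.0) < 3 * se


class TestDefects:
    def test_static_defect_scaling(self, gene_20kbp):
        geom, regions = gm.default_annotated_gene()
        q_i = np.ones(geom.n_sites)
        out = gm.apply_static_defects(q_i, regions)
        annotated = np.zeros(geom.n_sites, dtype=bool)
        for r in regions:
            annotated[r.site_range[0] - 1 : r.site_range[1]] = True
        assert np.all(out[annotated] == 0.5)
        assert np.all(out[~annotated] == 1.0)
        # a GC-slowed exon site 0.86q halves to the documented minimum 0.43q
        assert 0.86 * 0.5 == pytest.approx(0.43)

    def test_static_defect_identity_on_empty_regions(self):
        q_i = np.full(8, 1.3)
        np.testing.assert_array_equal(gm.apply_static_defects(q_i, []), q_i)

    def test_dynamic_defect_scaling(self):
        geom, regions = gm.default_annotated_gene()
        h_c_m = np.full(geom.n_units, 0.1)
        h_o_m = np.full(geom.n_units, 0.01)
        hc, ho = gm.apply_dynamic_defects(h_c_m, h_o_m, regions)
        annotated = np.zeros(geom.n_units, dtype=bool)
        for r in regions:
            for m in r.nucleosome_indices:
                annotated[m - 1] = True
        assert np.all(hc[annotated] == pytest.approx(0.125))
        assert np.all(ho[annotated] == pytest.approx(0.0075))
        assert np.all(hc[~annotated] == 0.1)
        assert np.all(ho[~annotated] == 0.01)

    def test_overlapping_regions_rejected(self):
        r1 = gm.RegionAnnotation("cpg_island", (1, 32), tuple(range(1, 9)))
        r2 = gm.RegionAnnotation("exon", (30, 37), (8, 9))
        with pytest.raises(ValueError, match="overlap"):
            gm.apply_static_defects(np.ones(400), [r1, r2])


class TestDefaultAnnotatedGene:
    def test_region_counts(self):
        geom, regions = gm.default_annotated_gene()
        assert len(regions) == 8  # CpG island + 7 exons
        assert regions[0].label == "cpg_island"
        assert regions[0].site_range == (1, 32)
        n_nucs = sum(len(r.nucleosome_indices) for r in regions)
        n_sites = sum(r.site_range[1] - r.site_range[0] + 1 for r in regions)
        assert n_nucs == 22  # 8 island + 7 exons x 2
        assert n_sites == 88  # 32 + 7 x 8

    def test_exons_evenly_spaced_and_disjoint(self):
        _, regions = gm.default_annotated_gene()
        starts = [r.site_range[0] for r in regions[1:]]
        gaps = np.diff(starts)
        assert gaps.max() - gaps.min() <= 8  # within one unit of even spacing
        spans = sorted(r.site_range for r in regions)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_island_only_variant(self):
        geom, regions = gm.default_annotated_gene(2_000, n_exons=0)
        assert len(regions) == 1
        assert regions[0].site_range == (1, 32)

    def test_too_short_gene_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            gm.default_annotated_gene(2_000, n_exons=7)


class TestSerialization:
    def test_tables_round_trip(self):
        geom, regions = gm.default_annotated_gene()
        q_i = gm.sample_gc_advance_rates(geom, 1.0, seed=9)
        h_c_m, h_o_m = gm.sample_gc_nucleosome_rates(geom, 0.1, 0.01, seed=9)
        params = gm.RateParams(0.05, 1.0, q_i, h_c_m, h_o_m)
        sites, nucs = gm.rates_tables(geom, params, regions)
        geom2 = gm.geometry_from_table(sites, geom.k_L, geom.k_N)
        assert geom2 == geom
        np.testing.assert_array_equal(sites["q_i"].to_numpy(), params.q_site)
        np.testing.assert_array_equal(nucs["h_c_m"].to_numpy(), params.h_c_m)
        assert (nucs["annotation"] != "").sum() == 22
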