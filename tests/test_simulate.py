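import numpy as np
import pytest
from scipy.stats import chisquare

import hotqtl as h
from hotqtl.simulate import SummarizedQTLSpec, genetic_variance


class TestBackcross:
    def test_zero_distance_loci_are_identical(self, study_map):
        # an extra locus placed exactly at a marker shares its genotype column
        G, extras = h.simulate_backcross(study_map, 50, 3,
                                         extra_loci={"1": np.array([2.0])})
        assert np.array_equal(G[:, 1], extras[("1", 2.0)])

    def test_allele_frequency_half(self, study_map):
        G, _ = h.simulate_backcross(study_map, 10000, 0)
        freq = G.mean(axis=0)
        se = np.sqrt(0.25 / 10000)
        assert np.abs(freq - 0.5).max() <= 4 * se  # 250 markers, max over many

    def test_adjacent_recombination_matches_haldane(self, study_map):
        G, _ = h.simulate_backcross(study_map, 10000, 1)
        r_expected = h.haldane_r(2.0)
        se = np.sqrt(r_expected * (1 - r_expected) / 10000)
        for j in (0, 20, 48):
            r_emp = (G[:, j] != G[:, j + 1]).mean()
            assert abs(r_emp - r_expected) <= 3.5 * se

    def test_seed_reproducibility(self, study_map):
        G1, _ = h.simulate_backcross(study_map, 30, 7)
        G2, _ = h.simulate_backcross(study_map, 30, 7)
        G3, _ = h.simulate_backcross(study_map, 30, 8)
        assert np.array_equal(G1, G2)
        assert not np.array_equal(G1, G3)


class TestGeneticVariance:
    def test_monogenic(self):
        assert genetic_variance([("1", 50.0)], [2.0]) == pytest.approx(1.0)

    def test_linked_pair_includes_covariance(self):
        lam = h.linkage_lambda(10.0)
        got = genetic_variance([("1", 10.0), ("1", 20.0)], [1.0, -1.0])
        assert got == pytest.approx(0.25 + 0.25 - 2 * lam / 4)

    def test_unlinked_pair_has_no_covariance(self):
        got = genetic_variance([("1", 10.0), ("2", 10.0)], [1.0, 1.0])
        assert got == pytest.approx(0.5)


class TestReferenceDesign:
    def test_shape_and_structure(self, study_sim):
        cross, truth, _ = study_sim
        assert cross.n_individuals == 100
        assert cross.n_traits == 600
        assert cross.genetic_map.n_markers == 250
        counts = truth.groupby("hotspot")["trait"].nunique()
        assert counts["A"] == 100 and counts["B"] == 300 and counts["C"] == 200
        # 40 hotspot-A traits are digenic or trigenic with genes on chr 2 and/or 4
        multi = truth[truth["hotspot"] == "A"].groupby("trait").size()
        assert (multi > 1).sum() == 40
        sec = truth[(truth["hotspot"] == "A") & (truth["position_cM"] != 50.0)]
        assert set(sec["chromosome"]) <= {"2", "4"}

    def test_heritability_ranges(self, study_sim):
        _, truth, _ = study_sim
        per_trait = truth.groupby(["trait", "hotspot"])["h2"].first().reset_index()
        a = per_trait[per_trait["hotspot"] == "A"]["h2"]
        c = per_trait[per_trait["hotspot"] == "C"]["h2"]
        assert a.between(0.30, 0.45).all()
        assert c.between(0.10, 0.20).all()

    def test_realized_h2_matches_target(self, study_sim):
        # squared correlation between a monogenic trait and its gene genotype
        # averages to the drawn h2 (sampling error shrinks over 150 traits)
        cross, truth, _ = study_sim
        # the hotspot-B gene at 50 cM coincides with a marker on the default map
        j = int(np.flatnonzero(
            cross.genetic_map.chromosomes[2].positions == 50.0)[0])
        col = sum(c.n_markers for c in cross.genetic_map.chromosomes[:2]) + j
        g = cross.genotypes[:, col].astype(float)
        b = truth[(truth["hotspot"] == "B")]
        r2 = []
        for _, row in b.iterrows():
            y = cross.phenotypes[:, cross.trait_names.index(row["trait"])]
            r2.append(np.corrcoef(y, g)[0, 1] ** 2)
        assert np.mean(r2) == pytest.approx(b["h2"].mean(), abs=0.04)

    def test_pairwise_correlation_spread(self, study_sim):
        # the study's trait-correlation distribution: roughly -0.4..0.7 with a
        # small positive mean
        cross, _, _ = study_sim
        rng = np.random.default_rng(2)
        idx = rng.choice(600, size=80, replace=False)
        C = np.corrcoef(cross.phenotypes[:, idx].T)
        off = C[np.triu_indices_from(C, k=1)]
        assert off.min() < -0.2 and off.max() > 0.5
        assert 0.0 < off.mean() < 0.25

    def test_determinism(self):
        c1, t1 = h.simulate_reference_design(9)
        c2, t2 = h.simulate_reference_design(9)
        assert np.array_equal(c1.phenotypes, c2.phenotypes)
        assert t1.equals(t2)


class TestNullData:
    def test_noise_mode_false_positive_rate(self, study_map):
        # at a fixed single-trait GWER-5% LOD threshold, about 5% of pure-noise
        # traits yield a detection somewhere in the genome
        cross, _ = h.simulate_null(study_map, 100, 300, seed=17, mode="noise")
        lod = h.hk_scan(cross)
        qs = h.detect_qtl(lod, 2.47)
        frac = len(qs.counts_per_trait()) / 300
        assert 0.01 <= frac <= 0.12

    def test_monogenic_positions_uniform(self, study_map):
        _, truth = h.simulate_null(study_map, 10, 4000, seed=18, mode="monogenic")
        bins = h.build_bins(study_map, 10.0)
        w = [bins.position_to_bin(r["chromosome"], r["position_cM"])
             for _, r in truth.iterrows()]
        counts = np.bincount(w, minlength=bins.W)
        assert chisquare(counts).pvalue > 0.01

    def test_null_qtlset_deterministic(self, study_bins):
        a = h.simulate_null_qtlset(study_bins, 30, 5)
        b = h.simulate_null_qtlset(study_bins, 30, 5)
        assert a.to_frame().equals(b.to_frame())


class TestSummarized:
    def _spec(self, **kw):
        defaults = dict(genetic_map=h.GeneticMap.equally_spaced(),
                        n_traits=20, n_qtl=400)
        defaults.update(kw)
        return SummarizedQTLSpec(**defaults)

    def test_point_mass_widths(self):
        spec = self._spec(width_classes=((0.0, 0.0, 1.0),))
        df = h.simulate_summarized(spec, 1)
        assert (df["start_cM"] == df["end_cM"]).all()

    def test_width_class_frequencies(self):
        spec = self._spec(n_qtl=4000)
        df = h.simulate_summarized(spec, 2)
        widths = (df["end_cM"] - df["start_cM"]).to_numpy()
        # class (0,0.5] has probability 0.4614 + 0.0376 point mass below it
        frac_small = (widths <= 0.5).mean()
        p = 0.4614 + 0.0376
        se = np.sqrt(p * (1 - p) / 4000)
        assert abs(frac_small - p) <= 3.5 * se

    def test_unclustered_architecture_is_flat(self):
        # with clustering off the five-times-mean rule flags nothing
        spec = self._spec(n_qtl=5000)
        df = h.simulate_summarized(spec, 3)
        path_free = df
        import io as _io
        buf = _io.StringIO()
        path_free.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        qs, model = h.read_summarized_qtl(buf, genetic_map=spec.genetic_map)
        bins = h.build_bins(spec.genetic_map, 2.0)
        arch = h.build_eqf(qs, bins, model=model).architecture()
        assert arch.Fw.max() / arch.Fw.mean() < 5.0

    def test_clustering_creates_hotspots(self):
        spec = self._spec(n_qtl=2000, clustering=0.3,
                          hotspot_positions=(("3", 50.0),))
        df = h.simulate_summarized(spec, 4)
        centre = (df["start_cM"] + df["end_cM"]) / 2
        near = ((df["chromosome"] == "3") & (centre - 50).abs().lt(2)).mean()
        assert near > 0.2

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            self._spec(width_classes=((0.0, 0.0, 0.5),))
        with pytest.raises(ValueError):
            self._spec(n_qtl=5, n_traits=10)
        with pytest.raises(ValueError):
            self._spec(clustering=0.5)
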