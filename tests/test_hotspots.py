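import numpy as np
import pytest
from scipy.stats import ks_2samp

import hotqtl as h
from hotqtl.hotspots import TraitGroups, _classify_trend


def _qtl(trait, chrom="1", peak=5.0, width=4.0, sd=1.0):
    start = max(peak - width / 2, 0.0)
    end = min(peak + width / 2, 100.0)
    return h.QTLInterval(trait=trait, chromosome=chrom, peak=peak,
                         start=start, end=end, sd=sd, lod=4.0)


class _ZeroRng:
    """Stub RNG drawing only zero offsets (identity permutation)."""

    def integers(self, *a, **k):
        return 0

    def uniform(self, lo, hi):
        return 0.0


class TestGroupTraits:
    def test_all_distinct_bins_gives_singleton_groups(self, study_bins,
                                                      singleton_qtlset):
        g = h.group_traits(singleton_qtlset, study_bins)
        assert g.R == 50 and len(g.trunks) == 0 and len(g.free) == 50

    def test_all_traits_in_one_bin_gives_one_group(self, study_bins):
        qs = h.QTLSet(qtls=[_qtl(f"t{i}", peak=50.5) for i in range(8)])
        g = h.group_traits(qs, study_bins)
        assert g.R == 1
        assert g.group_sizes()[0] == 8
        (trunk,) = g.trunks.values()
        assert len(trunk) == 8 and len(g.free) == 0

    def test_transitive_closure_over_shared_bins(self, study_bins):
        # t1,t2 share bin(10); t2,t3 share bin(18); t4 alone
        qs = h.QTLSet(qtls=[
            _qtl("t1", peak=10.5), _qtl("t2", peak=10.9),
            _qtl("t2", peak=18.3), _qtl("t3", peak=18.8),
            _qtl("t4", peak=70.0)])
        g = h.group_traits(qs, study_bins)
        got = g.group_of_trait
        assert got["t1"] == got["t2"] == got["t3"] != got["t4"]
        assert g.R == 2
        assert sorted(tuple(v) for v in g.trunks.values()) == [(0, 1), (2, 3)]
        assert list(g.free) == [4]

    def test_single_trait_pileup_is_dissolved(self, study_bins):
        # two QTL of the same trait in one bin do not form a trunk
        qs = h.QTLSet(qtls=[_qtl("t1", peak=10.2), _qtl("t1", peak=10.8)])
        g = h.group_traits(qs, study_bins)
        assert len(g.trunks) == 0 and len(g.free) == 2


class TestPermutations:
    def _grouped_set(self, study_bins):
        qs = h.QTLSet(qtls=[
            _qtl("t1", "1", 50.5), _qtl("t2", "1", 51.0), _qtl("t3", "1", 50.2),
            _qtl("t4", "2", 30.0, width=6.0, sd=1.5), _qtl("t5", "3", 80.0)])
        emat = h.build_eqf(qs, study_bins)
        return qs, emat, h.group_traits(qs, study_bins)

    def test_zero_offsets_are_identity(self, study_bins):
        qs, emat, groups = self._grouped_set(study_bins)
        perm = h.permute_eqf_bins(emat, groups, _ZeroRng())
        assert all(np.array_equal(a, b) for a, b in zip(perm.qtl_bins, emat.qtl_bins))

    def test_row_sums_conserved_exactly(self, study_bins):
        qs, emat, groups = self._grouped_set(study_bins)
        rng = np.random.default_rng(0)
        perm = h.permute_eqf_bins(emat, groups, rng)
        assert np.allclose(perm.F.sum(axis=1), emat.F.sum(axis=1), atol=1e-12)

    def test_mass_multiset_unchanged_by_bin_shift(self, study_bins):
        qs, emat, groups = self._grouped_set(study_bins)
        rng = np.random.default_rng(1)
        perm = h.permute_eqf_bins(emat, groups, rng)
        for a, b in zip(perm.qtl_masses, emat.qtl_masses):
            assert np.allclose(np.sort(a), np.sort(b))

    def test_trunk_moves_jointly(self, study_bins):
        qs, emat, groups = self._grouped_set(study_bins)
        rng = np.random.default_rng(2)
        perm = h.permute_eqf_bins(emat, groups, rng)
        (trunk,) = groups.trunks.values()
        shifts = {(perm.qtl_bins[i][0] - emat.qtl_bins[i][0]) % study_bins.W
                  for i in trunk}
        assert len(shifts) == 1

    def test_interval_permutation_conserves_mass(self, study_bins):
        qs, emat, groups = self._grouped_set(study_bins)
        rng = np.random.default_rng(3)
        perm = h.permute_qtl_intervals(qs, groups, study_bins, rng)
        for m in perm.qtl_masses:
            assert m.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(perm.F.sum(axis=1), emat.F.sum(axis=1), atol=1e-9)

    def test_interval_longer_than_genome_rejected(self):
        gmap = h.GeneticMap((h.Chromosome("1", 9.0, np.array([0.0, 9.0])),))
        bins = h.build_bins(gmap, 2.0)
        qs = h.QTLSet(qtls=[h.QTLInterval(trait="t1", chromosome="1", peak=5.0,
                                          start=-3.0, end=12.0, sd=5.0, lod=4.0)])
        with pytest.raises(ValueError, match="longer than the genome"):
            h.permute_qtl_intervals(qs, TraitGroups.all_free(1, ["t1"]), bins,
                                    np.random.default_rng(0))

    def test_point_qtl_occupancy_uniform_over_bins(self, study_bins):
        # multinomial oracle: a single 1-bin QTL lands in each of the 250 bins
        # with frequency 1/250 (within 3 SE over 10,000 shifts)
        qs = h.QTLSet(qtls=[h.QTLInterval(trait="t1", chromosome="1", peak=50.0,
                                          start=50.0, end=50.0, sd=1e-6, lod=5.0)])
        groups = h.group_traits(qs, study_bins)
        rng = np.random.default_rng(0)
        counts = np.zeros(study_bins.W)
        for _ in range(10000):
            perm = h.permute_qtl_intervals(qs, groups, study_bins, rng)
            counts[perm.qtl_bins[0][0]] += 1
        p = 1.0 / study_bins.W
        se = np.sqrt(10000 * p * (1 - p))
        assert np.abs(counts - 10000 * p).max() <= 3 * se


class TestGammaThresholds:
    def test_single_unit_qtl_gives_gamma1_of_one(self, study_bins):
        qs = h.QTLSet(qtls=[h.QTLInterval(trait="t1", chromosome="1", peak=50.0,
                                          start=50.0, end=50.0, sd=1e-6, lod=5.0)])
        emat = h.build_eqf(qs, study_bins)
        thr = h.gamma_thresholds(emat, h.group_traits(qs, study_bins),
                                 B=200, alpha=0.05, seed=0)
        assert thr.gammas[0] == pytest.approx(1.0)

    def test_ladder_non_increasing(self, study_bins, singleton_qtlset):
        emat = h.build_eqf(singleton_qtlset, study_bins)
        thr = h.gamma_thresholds(emat, h.group_traits(singleton_qtlset, study_bins),
                                 B=300, seed=1)
        assert np.all(np.diff(thr.gammas) <= 1e-12)

    def test_degenerate_empty_input_gives_zero_thresholds(self, study_bins):
        emat = h.build_eqf(h.QTLSet(qtls=[]), study_bins)
        thr = h.gamma_thresholds(emat, TraitGroups.all_free(0, []), B=100, seed=0)
        assert np.all(thr.gammas == 0.0)

    def test_k_closes_ladder_at_beta(self, study_bins, singleton_qtlset):
        emat = h.build_eqf(singleton_qtlset, study_bins)
        thr = h.gamma_thresholds(emat, h.group_traits(singleton_qtlset, study_bins),
                                 B=300, seed=2)
        assert thr.gammas[thr.k - 1] >= thr.beta
        if thr.k < len(thr.gammas):
            assert thr.gammas[thr.k] < thr.beta

    def test_deterministic_under_seed(self, study_bins, singleton_qtlset):
        emat = h.build_eqf(singleton_qtlset, study_bins)
        g = h.group_traits(singleton_qtlset, study_bins)
        t1 = h.gamma_thresholds(emat, g, B=200, seed=42)
        t2 = h.gamma_thresholds(emat, g, B=200, seed=42)
        assert np.array_equal(t1.gammas, t2.gammas) and t1.beta == t2.beta

    def test_grouped_equals_qmethod_for_singletons(self, study_bins,
                                                   singleton_qtlset):
        # all-singleton monogenic input: grouped permutation is distributionally
        # identical to the Q-method (KS on the F*(1) samples at the 5% level)
        emat = h.build_eqf(singleton_qtlset, study_bins)
        grouped = h.gamma_thresholds(emat, h.group_traits(singleton_qtlset, study_bins),
                                     B=500, seed=7)
        free = h.gamma_thresholds(emat,
                                  TraitGroups.all_free(emat.n_qtl, emat.traits),
                                  B=500, seed=8)
        assert ks_2samp(grouped.samples[:, 0], free.samples[:, 0]).pvalue > 0.05

    def test_schemes_concordant_on_monogenic_data(self, study_bins):
        # EQF-bin and QTL-interval schemes agree within Monte-Carlo error
        cross, _ = h.simulate_null(h.GeneticMap.equally_spaced(), 100, 40, 99,
                                   mode="monogenic")
        qs = h.detect_qtl(h.hk_scan(cross), 2.5)
        emat = h.build_eqf(qs, study_bins)
        groups = h.group_traits(qs, study_bins)
        tb = h.gamma_thresholds(emat, groups, B=500, seed=11, scheme="eqf-bin",
                                keep_samples=False)
        ti = h.gamma_thresholds(emat, groups, B=500, seed=12, scheme="qtl-interval",
                                keep_samples=False)
        for n in range(4):
            assert ti.gammas[n] == pytest.approx(tb.gammas[n], rel=0.10)


class TestCallHotspots:
    def _arch_and_thresholds(self, study_bins, singleton_qtlset):
        emat = h.build_eqf(singleton_qtlset, study_bins)
        thr = h.gamma_thresholds(emat, h.group_traits(singleton_qtlset, study_bins),
                                 B=300, seed=5)
        return emat.architecture(), thr, emat

    def test_threshold_above_maximum_gives_empty_report(self, study_bins,
                                                        singleton_qtlset):
        arch, thr, _ = self._arch_and_thresholds(study_bins, singleton_qtlset)
        thr.gammas = np.full_like(thr.gammas, arch.Fw.max() + 1)
        thr.k = 1
        assert h.call_hotspots(arch, thr, n=1).n_called == 0

    def test_reports_nested_in_n(self, study_bins, singleton_qtlset):
        arch, thr, emat = self._arch_and_thresholds(study_bins, singleton_qtlset)
        prev: set = set()
        for n in range(1, min(thr.k, 6) + 1):
            bins_called = set(h.call_hotspots(arch, thr, n=n).bins)
            assert prev.issubset(bins_called)
            prev = bins_called

    def test_n_beyond_k_is_an_error_mentioning_beta(self, study_bins,
                                                    singleton_qtlset):
        arch, thr, _ = self._arch_and_thresholds(study_bins, singleton_qtlset)
        with pytest.raises(ValueError, match="beta"):
            h.call_hotspots(arch, thr, n=thr.k + 1)

    def test_ge_flag_includes_borderline_equality(self, study_bins,
                                                  singleton_qtlset):
        arch, thr, _ = self._arch_and_thresholds(study_bins, singleton_qtlset)
        thr.gammas = np.full_like(thr.gammas, arch.Fw.max())
        thr.k = 1
        assert h.call_hotspots(arch, thr, n=1).n_called == 0
        assert h.call_hotspots(arch, thr, n=1, ge=True).n_called >= 1


class TestTopGammaProfile:
    def test_trend_classification_rule(self):
        assert _classify_trend([2, 3, 4, 5, 6], [2, 3, 4, 6, 7]) == "increasing"
        assert _classify_trend([2, 3, 4, 5, 6], [3, 3, 2, 2, 2]) == "decreasing"
        assert _classify_trend([2, 3, 4, 5, 6], [1, 1, 1, 1, 1]) == "flat"
        assert _classify_trend([2, 3, 4, 5, 6], [2, 1, 3, 1, 2]) == "flat"

    def _ladder(self, study_bins, fw_by_L):
        ladder = []
        for L, fw in fw_by_L.items():
            Fw = np.zeros(study_bins.W)
            Fw[10] = fw
            arch = h.EQFArchitecture(bins=study_bins, Fw=Fw)
            gammas = np.array([50.0, 20.0, 10.0, 5.0, 2.0])
            thr = h.GammaThresholds(alpha=0.05, B=100, scheme="eqf-bin",
                                    gammas=gammas, beta=2.0, k=5)
            ladder.append((L, arch, thr))
        return ladder

    def test_all_ns_gives_type_none(self, study_bins):
        ladder = self._ladder(study_bins, {2: 1.0, 3: 1.0, 4: 1.0})
        p = h.top_gamma_profile(10, ladder)
        assert p.hotspot_type == "none" and all(n is None for n in p.n_values)

    def test_increasing_profile_is_type_i(self, study_bins):
        ladder = self._ladder(study_bins, {2: 60.0, 3: 25.0, 4: 12.0, 5: 6.0, 6: 3.0})
        p = h.top_gamma_profile(10, ladder)
        assert p.n_values == [1, 2, 3, 4, 5]
        assert p.trend == "increasing" and p.hotspot_type == "i"

    def test_decreasing_profile_is_type_ii(self, study_bins):
        ladder = self._ladder(study_bins, {2: 12.0, 3: 12.0, 4: 25.0, 5: 60.0})
        p = h.top_gamma_profile(10, ladder)
        assert p.trend == "decreasing" and p.hotspot_type == "ii"

    def test_n_monotone_in_fw_for_fixed_thresholds(self, study_bins):
        ladder = self._ladder(study_bins, {2: 60.0})
        L, arch, thr = ladder[0]
        ns = []
        for fw in (60.0, 25.0, 12.0, 6.0):
            arch.Fw[10] = fw
            ns.append(h.top_gamma_profile(10, [(L, arch, thr)]).n_values[0])
        assert ns == sorted(ns)

    def test_threshold_equality_counts_as_significant(self, study_bins):
        ladder = self._ladder(study_bins, {2: 20.0})
        p = h.top_gamma_profile(10, ladder)
        assert p.n_values[0] == 2  # gamma(2) = 20 <= Fw = 20
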