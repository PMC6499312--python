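"""Mutation context: breakpoint-proximal SNV rates, kataegis, contig
mismatch/indel rates, category clustering against a brute-force linkage
oracle, and the 96-context matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import crisischain as cc


def _snvs_at(sample, chrom, positions):
    return [cc.SNVRecord(sample, chrom, int(p), "C", "T") for p in positions]


class TestSvMutationRates:
    def _genome(self):
        return cc.GenomeModel({"chr1": 2_000_000})

    def test_identical_snv_sets_give_fold_one(self):
        positions = np.arange(1000, 1_900_000, 5_000)
        snvs = {s: _snvs_at(s, "chr1", positions) for s in ("a", "b", "c")}
        bps = [("a", "chr1", 500_000), ("a", "chr1", 900_000)]
        summary = cc.sv_mutation_rates(bps, snvs, self._genome())
        assert summary.fold_change == pytest.approx(1.0)

    def test_planted_excess_recovered(self):
        rng = np.random.default_rng(51)
        base_rate = 1e-4
        g = self._genome()
        snvs = {s: _snvs_at(s, "chr1", rng.integers(0, 2_000_000,
                                                    int(base_rate * 2_000_000)))
                for s in ("a", "b", "c", "d")}
        bps = [("a", "chr1", int(p))
               for p in np.linspace(50_000, 1_950_000, 25)]
        extra = []
        for _, c, p in bps:
            # raise interval rate from r to 8r: add 7r * 20 kb mutations
            n_extra = rng.poisson(7 * base_rate * 20_000)
            extra += _snvs_at("a", c, rng.integers(p - 10_000, p + 10_000, n_extra))
        snvs["a"] = snvs["a"] + extra
        summary = cc.sv_mutation_rates(bps, snvs, g)
        n_s = sum(r.count for r in summary.records)
        se = summary.fold_change * np.sqrt(1 / max(n_s, 1) + 1 / 100)
        assert abs(summary.fold_change - 8.0) < 3 * max(se, 0.8)
        assert summary.pvalue < 0.01

    def test_clipped_interval_flagged(self):
        snvs = {"a": _snvs_at("a", "chr1", [1000, 2000]),
                "b": _snvs_at("b", "chr1", [1500])}
        summary = cc.sv_mutation_rates([("a", "chr1", 5_000)], snvs, self._genome())
        (rec,) = summary.records
        assert rec.clipped and rec.interval == (0, 15_000)
        assert rec.rate == pytest.approx(2 / 15_000)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            cc.sv_mutation_rates([], {"a": []}, self._genome())

    def test_fold_change_scale_invariant(self):
        rng = np.random.default_rng(52)
        pos = rng.integers(0, 2_000_000, 300)
        snvs1 = {"a": _snvs_at("a", "chr1", pos),
                 "b": _snvs_at("b", "chr1", pos[:150])}
        bps = [("a", "chr1", 1_000_000)]
        f1 = cc.sv_mutation_rates(bps, snvs1, self._genome()).fold_change
        # doubling every catalog leaves the fold unchanged
        snvs2 = {k: v + [cc.SNVRecord(r.sample, r.chrom, r.pos + 1, "C", "T")
                         for r in v] for k, v in snvs1.items()}
        f2 = cc.sv_mutation_rates(bps, snvs2, self._genome()).fold_change
        assert f1 == pytest.approx(f2)


class TestKataegis:
    def test_sparse_uniform_snvs_no_clusters(self):
        snvs = _snvs_at("s", "chr1", np.arange(0, 10**6, 20_000))
        assert cc.detect_kataegis(snvs) == []

    def test_planted_cluster_contains_all(self):
        snvs = cc.plant_kataegis([], "s", "chr1", 50_000, count=10, span=1000,
                                 seed=53)
        (cl,) = cc.detect_kataegis(snvs)
        assert cl.count == 10 and cl.mean_distance <= 1000

    def test_two_distant_plants_give_two_clusters(self):
        snvs = cc.plant_kataegis([], "s", "chr1", 50_000, 8, 800, seed=54)
        snvs = cc.plant_kataegis(snvs, "s", "chr1", 1_050_000, 8, 800, seed=55)
        clusters = cc.detect_kataegis(snvs)
        assert len(clusters) == 2

    def test_clusters_disjoint_and_maximal(self):
        rng = np.random.default_rng(56)
        snvs = _snvs_at("s", "chr1", rng.integers(0, 10**6, 200))
        snvs = cc.plant_kataegis(snvs, "s", "chr1", 400_000, 12, 2_000, seed=57)
        clusters = cc.detect_kataegis(snvs)
        for a, b in zip(clusters, clusters[1:]):
            assert a.end <= b.start or a.chrom != b.chrom

    def test_min_count_respected(self):
        snvs = cc.plant_kataegis([], "s", "chr1", 50_000, count=5, span=500,
                                 seed=58)
        assert cc.detect_kataegis(snvs, min_count=6) == []


class TestKataegisOverlap:
    def test_empty_clusters_give_one(self, genome):
        assert cc.kataegis_sv_overlap([], [("chr1", 0, 10**6)], genome) == 1.0

    def test_colocated_plants_significant(self, genome):
        from crisischain.mutations import KataegisCluster
        clusters = [KataegisCluster("s", "chr1", s, s + 1000, 8, 100.0)
                    for s in range(1_000_000, 21_000_000, 2_000_000)]
        chains = [("chr1", s, s + 50_000)
                  for s in range(1_000_000, 21_000_000, 2_000_000)]
        p = cc.kataegis_sv_overlap(clusters, chains, genome)
        assert p < 0.01

    def test_disjoint_plants_not_significant(self, genome):
        from crisischain.mutations import KataegisCluster
        clusters = [KataegisCluster("s", "chr1", 5_000_000, 5_001_000, 8, 100.0)]
        chains = [("chr2", 10_000_000, 10_050_000)]
        assert cc.kataegis_sv_overlap(clusters, chains, genome) > 0.2


class TestContigMutationRates:
    def _paths(self, reference, spec, n, seed0):
        paths, contigs = {}, {}
        for i in range(n):
            sc = cc.make_contig(reference, spec, seed=seed0 + i, contig_id=f"c{i}")
            path = cc.best_path(cc.build_graph(sc.candidates))
            paths[f"c{i}"] = path
            contigs[f"c{i}"] = sc.sequence
        return paths, contigs

    def test_zero_mutation_contigs_give_zero_rates(self, contig_reference):
        # microhomology junctions rewrite the per-contig reference copy, so
        # rates are checked against each contig's own returned reference
        spec = cc.ContigSpec(n_fragments=5, n_decoys=0)
        for seed in (60, 61, 62):
            sc = cc.make_contig(contig_reference, spec, seed=seed)
            path = cc.best_path(cc.build_graph(sc.candidates))
            res = cc.contig_mutation_rates({"c": path}, {"c": sc.sequence},
                                           sc.reference)
            assert (res.per_junction.mismatch_rate == 0).all()
            assert (res.per_junction.indel_rate == 0).all()

    def test_planted_mismatch_fold_recovered(self):
        ref = cc.random_reference({"refA": 60_000, "refB": 60_000}, seed=61)
        sv_spec = cc.ContigSpec(n_fragments=8, mismatch_rate=0.01, n_decoys=0,
                                p_microhomology=0.0)
        base_spec = cc.ContigSpec(n_fragments=1, mismatch_rate=0.0026, n_decoys=0)
        paths, contigs = self._paths(ref, sv_spec, 10, 70)
        bpaths, bcontigs = self._paths(ref, base_spec, 60, 700)
        res = cc.contig_mutation_rates(paths, contigs, ref,
                                       baseline_paths=bpaths,
                                       baseline_contigs=bcontigs)
        assert res.mismatch_fold == pytest.approx(0.01 / 0.0026, rel=0.35)
        assert res.p_mismatch < 0.01


class TestCategorizeAndCluster:
    def test_category_id_bit_order(self):
        assert cc.category_id(False, False, False) == 0
        assert cc.category_id(False, False, True) == 1
        assert cc.category_id(False, True, False) == 2
        assert cc.category_id(True, False, False) == 4
        assert cc.category_id(True, True, True) == 7

    def _table(self, rng, n=400, archetypes=None):
        rows = []
        for _ in range(n):
            ch, cx, it = (bool(rng.integers(2)) for _ in range(3))
            mh, ins, mm, ind = 3.0, 2.0, 0.01, 0.002
            if archetypes:
                mh, ins, mm, ind = archetypes(ch, cx, it)
            rows.append({"chained": ch, "complex": cx, "inter": it,
                         "microhomology": mh + rng.normal(0, 0.01),
                         "insertion": ins, "mismatch_rate": mm,
                         "indel_rate": ind})
        return pd.DataFrame(rows)

    def test_counts_partition_all_svs(self):
        rng = np.random.default_rng(62)
        df = self._table(rng)
        df["category"] = [cc.category_id(c, x, i) for c, x, i in
                          zip(df.chained, df["complex"], df.inter)]
        assert df.category.value_counts().sum() == len(df)
        assert set(df.category) <= set(range(8))

    def test_identical_features_give_single_cluster(self):
        rows = [{"chained": c, "complex": x, "inter": i,
                 "microhomology": 3.0, "insertion": 2.0,
                 "mismatch_rate": 0.01, "indel_rate": 0.002}
                for c in (False, True) for x in (False, True)
                for i in (False, True)]
        res = cc.categorize_and_cluster(pd.DataFrame(rows))
        assert set(res.clusters.values()) == {1}

    def test_three_archetypes_recovered(self):
        rng = np.random.default_rng(64)

        def arch(ch, cx, it):
            if it and cx:
                return 12.0, 10.0, 0.05, 0.01   # complex interchromosomal
            if it:
                return 8.0, 2.0, 0.02, 0.002
            return 2.0, 1.0, 0.005, 0.001
        res = cc.categorize_and_cluster(self._table(rng, archetypes=arch))
        groups = {}
        for cat, lab in res.clusters.items():
            inter, cx = bool(cat & 1), bool(cat & 2)
            groups.setdefault((inter, cx) if inter else ("intra",), set()).add(lab)
        assert len(set(res.clusters.values())) == 3
        # all intrachromosomal categories land in one cluster
        assert len(groups[("intra",)]) == 1

    def test_linkage_matches_brute_force_average(self):
        rng = np.random.default_rng(65)
        pts = rng.normal(size=(8, 4))
        link = hierarchy.linkage(pts, method="average")
        # brute-force O(n^3) average linkage
        clusters = {i: [i] for i in range(8)}
        dist = {(i, j): float(np.linalg.norm(pts[i] - pts[j]))
                for i in range(8) for j in range(i + 1, 8)}
        heights = []
        nxt = 8
        while len(clusters) > 1:
            (a, b), h = min(
                (((a, b), np.mean([dist[tuple(sorted((x, y)))]
                                   for x in clusters[a] for y in clusters[b]]))
                 for a in clusters for b in clusters if a < b),
                key=lambda kv: kv[1])
            heights.append(h)
            clusters[nxt] = clusters.pop(a) + clusters.pop(b)
            nxt += 1
        assert np.allclose(sorted(link[:, 2]), sorted(heights))

    def test_single_category_errors(self):
        df = pd.DataFrame([{"chained": True, "complex": True, "inter": True,
                            "microhomology": 1.0, "insertion": 0.0,
                            "mismatch_rate": 0.0, "indel_rate": 0.0}])
        with pytest.raises(ValueError):
            cc.categorize_and_cluster(df)


class TestContextMatrix:
    def test_counts_and_strand_folding(self):
        ref = {"chr1": "ACGTACGTAC"}
        snvs = [cc.SNVRecord("s", "chr1", 1, "C", "T"),   # A[C>T]G
                cc.SNVRecord("s", "chr1", 2, "G", "A")]   # G>A folds to C>T: T[C>T]G... complement of ACG -> C G T
        m = cc.context_matrix(snvs, ref)
        assert m.sum() == 2
        # pos 1: A[C>T]G directly; pos 2: CGT G>A folds to A[C>T]G as well
        assert m["A[C>T]G"] == 2

    def test_mismatched_ref_base_skipped(self):
        ref = {"chr1": "AAAAA"}
        snvs = [cc.SNVRecord("s", "chr1", 2, "C", "T")]
        assert cc.context_matrix(snvs, ref).sum() == 0
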