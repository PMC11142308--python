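"""LD-proxy expansion, colocalization, target genes, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from asoc import assign_target_genes, colocalize, expand_ld_proxies, set_enrichment
from asoc.gwas import adjust_enrichment_pvalues

from conftest import rng_for


def gwas_table(rows):
    return pd.DataFrame(rows, columns=["locus_id", "index_snp_id", "chrom", "pos", "p_value"])


def ld_table(rows):
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


class TestExpandLdProxies:
    def test_threshold_boundary(self):
        gwas = gwas_table([("L1", "A", "chr1", 100, 1e-9)])
        ld = ld_table([("A", "B", 0.85), ("A", "C", 0.79), ("A", "D", 0.80)])
        (locus,) = expand_ld_proxies(gwas, ld, 0.8)
        assert set(locus.proxy_set) == {"A", "B", "D"}  # inclusive >= 0.8
        assert locus.proxy_set["A"] == 1.0

    def test_symmetrized_pairs(self):
        gwas = gwas_table([("L1", "A", "chr1", 100, 1e-9)])
        ld = ld_table([("B", "A", 0.9)])  # reversed orientation
        (locus,) = expand_ld_proxies(gwas, ld)
        assert "B" in locus.proxy_set

    def test_missing_index_warns_singleton(self):
        gwas = gwas_table([("L1", "Z", "chr1", 100, 1e-9)])
        ld = ld_table([("A", "B", 0.9)])
        with pytest.warns(UserWarning):
            (locus,) = expand_ld_proxies(gwas, ld)
        assert set(locus.proxy_set) == {"Z"}

    def test_matches_exhaustive_scan_oracle(self):
        rng = rng_for("ld_scan_oracle")
        snp_ids = [f"s{i}" for i in range(200)]
        idx = rng.choice(200, size=50, replace=False)
        gwas = gwas_table(
            [(f"L{k}", snp_ids[i], "chr1", int(rng.integers(1, 10**6)), 1e-8) for k, i in enumerate(idx)]
        )
        pairs = [
            (snp_ids[int(a)], snp_ids[int(b)], float(np.round(rng.uniform(0, 1), 3)))
            for a, b in rng.integers(0, 200, size=(2000, 2))
            if a != b
        ]
        ld = ld_table(pairs)
        loci = expand_ld_proxies(gwas, ld, 0.8)
        for locus in loci:
            want = {locus.index_snp_id}
            best: dict[str, float] = {}
            for a, b, r2 in pairs:
                if a == locus.index_snp_id:
                    best[b] = max(best.get(b, -1), r2)
                if b == locus.index_snp_id:
                    best[a] = max(best.get(a, -1), r2)
            want |= {s for s, r2 in best.items() if r2 >= 0.8 and s != locus.index_snp_id}
            assert set(locus.proxy_set) == want, locus.locus_id

    def test_invalid_r2(self):
        gwas = gwas_table([("L1", "A", "chr1", 1, 1e-9)])
        with pytest.raises(ValueError):
            expand_ld_proxies(gwas, ld_table([("A", "B", 1.2)]))


class TestColocalize:
    def _loci(self):
        gwas = gwas_table(
            [("L1", "A", "chr1", 1, 1e-9), ("L2", "B", "chr1", 2, 1e-9), ("L3", "C", "chr1", 3, 1e-9)]
        )
        ld = ld_table(
            [("A", "x1", 0.9), ("B", "x2", 0.85), ("C", "x3", 0.95), ("A", "shared", 0.9), ("B", "shared", 0.9)]
        )
        return expand_ld_proxies(gwas, ld)

    def test_no_asoc_no_hits(self):
        report = colocalize([], self._loci())
        assert report.n_loci_with_asoc == 0
        assert report.fraction_loci_hit == 0.0

    def test_all_planted_hit(self):
        report = colocalize(["x1", "x2", "x3"], self._loci())
        assert report.n_loci_with_asoc == 3
        assert report.fraction_loci_hit == 1.0

    def test_shared_snp_listed_under_both_loci(self):
        report = colocalize(["shared"], self._loci())
        assert report.n_loci_with_asoc == 2
        assert report.per_locus == {"L1": ["shared"], "L2": ["shared"]}

    def test_empty_locus_table_fraction_undefined(self):
        report = colocalize(["x1"], [])
        assert report.n_loci_total == 0
        assert report.fraction_loci_hit is None

    def test_order_invariance(self):
        loci = self._loci()
        a = colocalize(["x3", "x1"], loci)
        b = colocalize(["x1", "x3"], list(reversed(loci)))
        assert a.per_locus == b.per_locus
        assert a.n_loci_with_asoc == b.n_loci_with_asoc


class TestAssignTargetGenes:
    def test_two_genes_two_rows(self):
        abc = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100, 100],
                "end": [600, 600],
                "target_gene": ["G1", "G2"],
                "abc_score": [0.3, 0.1],
            }
        )
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [200], "snp_id": ["s1"]})
        out = assign_target_genes(snps, abc)
        assert sorted(out["target_gene"]) == ["G1", "G2"]

    def test_snp_outside_no_rows(self):
        abc = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200], "target_gene": ["G"], "abc_score": [0.2]}
        )
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [1000], "snp_id": ["s"]})
        assert len(assign_target_genes(snps, abc)) == 0

    def test_matches_brute_force_join(self):
        rng = rng_for("abc_join_oracle")
        abc = pd.DataFrame(
            {
                "chrom": [f"chr{int(c)}" for c in rng.integers(1, 3, size=50)],
                "start": rng.integers(0, 50_000, size=50),
                "target_gene": [f"g{i}" for i in range(50)],
                "abc_score": rng.uniform(0, 1, size=50),
            }
        )
        abc["end"] = abc["start"] + rng.integers(1, 2000, size=50)
        snps = pd.DataFrame(
            {
                "chrom": [f"chr{int(c)}" for c in rng.integers(1, 3, size=200)],
                "pos": rng.integers(1, 52_000, size=200),
                "snp_id": [f"s{i}" for i in range(200)],
            }
        )
        got = set(map(tuple, assign_target_genes(snps, abc)[["snp_id", "target_gene"]].to_numpy()))
        want = {
            (s.snp_id, e.target_gene)
            for s in snps.itertuples(index=False)
            for e in abc.itertuples(index=False)
            if s.chrom == e.chrom and e.start <= s.pos - 1 < e.end
        }
        assert got == want


class TestSetEnrichment:
    def test_saturation_fold_one(self):
        u = [f"s{i}" for i in range(10)]
        res = set_enrichment(u, u, u)
        assert res.fold == 1.0

    def test_independence_fold_one(self):
        u = [f"s{i}" for i in range(1000)]
        a = u[:100]
        b = u[90:190]
        res = set_enrichment(a, b, u)
        assert res.n_overlap == 10
        assert res.fold == 1.0

    def test_fold_four_fixture(self):
        u = [f"s{i}" for i in range(1000)]
        a = u[:50]
        b = u[30:130]
        assert len(set(a) & set(b)) == 20
        res = set_enrichment(a, b, u, method="fisher")
        assert res.fold == 4.0
        # fisher one-sided tail equals the hypergeometric survival tail
        assert res.p_value == pytest.approx(hypergeom.sf(19, 1000, 100, 50), rel=1e-9)

    def test_permutation_agrees_with_hypergeometric(self):
        u = [f"s{i}" for i in range(1000)]
        a = u[:50]
        b = u[30:130]
        res = set_enrichment(a, b, u, method="permutation", n_perm=100_000, seed=1)
        exact = hypergeom.sf(19, 1000, 100, 50)
        se = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(res.p_value - exact) < 3 * se + 2 / 100_000

    def test_errors(self):
        with pytest.raises(ValueError):
            set_enrichment([], ["a"], ["a"])
        with pytest.raises(ValueError):
            set_enrichment(["a"], ["a"], [])
        with pytest.raises(ValueError):
            set_enrichment(["z"], ["a"], ["a"])
        with pytest.raises(ValueError):
            set_enrichment(["a"], ["a"], ["a"], method="magic")

    def test_bh_over_multiple_annotations(self):
        u = [f"s{i}" for i in range(100)]
        results = [
            set_enrichment(u[:20], u[10:40], u),
            set_enrichment(u[:20], u[50:90], u),
        ]
        q = adjust_enrichment_pvalues(results)
        assert len(q) == 2 and np.all(q <= 1)
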