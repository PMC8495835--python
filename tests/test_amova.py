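"""AMOVA variance components against a brute-force oracle, and pairwise F_ST."""

from __future__ import annotations

import numpy as np
import pytest

from haplopop import GenotypeMatrix, MicrohapLocus, amova, pairwise_fst, per_locus_fst
from conftest import island_genotypes


# ---------------------------------------------------------------------------
# brute-force oracle: explicit pairwise-distance double sums per locus,
# Excoffier-style mean squares and unequal-size coefficients, components
# summed over loci.

def brute_force_components(geno: GenotypeMatrix, pops: list[str],
                           groups: list[str] | None):
    pop_names = sorted(set(pops))
    sig_a = sig_b = sig_c = 0.0
    for li in range(geno.n_loci):
        copies = []   # (allele, pop, group)
        for k, ind in enumerate(geno.individuals):
            a, b = geno.calls[li, k]
            if a == -1:
                continue
            g = groups[k] if groups else "all"
            copies.append((a, pops[k], g))
            copies.append((b, pops[k], g))
        n_t = len(copies)

        def ssd(subset):
            # (1/n) * sum_{i<j} delta^2 by direct double sum
            m = len(subset)
            if m == 0:
                return 0.0
            tot = 0.0
            for i in range(m):
                for j in range(i + 1, m):
                    tot += 0.0 if subset[i][0] == subset[j][0] else 1.0
            return tot / m

        ssd_total = ssd(copies)
        pops_here = sorted({c[1] for c in copies})
        groups_here = sorted({c[2] for c in copies})
        ssd_wp = sum(ssd([c for c in copies if c[1] == p]) for p in pops_here)
        P, G = len(pops_here), len(groups_here)
        n_p = {p: sum(1 for c in copies if c[1] == p) for p in pops_here}
        if groups:
            ssd_wg = sum(ssd([c for c in copies if c[2] == g]) for g in groups_here)
            ssd_ap = ssd_wg - ssd_wp
            ssd_ag = ssd_total - ssd_wg
            n_g = {g: sum(1 for c in copies if c[2] == g) for g in groups_here}
            group_of_pop = {c[1]: c[2] for c in copies}
            ratio_pg = sum(
                sum(n_p[p]**2 for p in pops_here if group_of_pop[p] == g) / n_g[g]
                for g in groups_here)
            n1 = (n_t - ratio_pg) / (P - G) if P > G else np.nan
            n2 = (ratio_pg - sum(v**2 for v in n_p.values()) / n_t) / (G - 1)
            n3 = (n_t - sum(v**2 for v in n_g.values()) / n_t) / (G - 1)
            ms_wp = ssd_wp / (n_t - P)
            ms_ap = ssd_ap / (P - G) if P > G else np.nan
            ms_ag = ssd_ag / (G - 1)
            c = ms_wp
            b_comp = (ms_ap - c) / n1 if P > G else np.nan
            a_comp = (ms_ag - c - n2 * b_comp) / n3
            sig_a += a_comp
            sig_b += b_comp
            sig_c += c
        else:
            ssd_ap = ssd_total - ssd_wp
            ms_wp = ssd_wp / (n_t - P)
            ms_ap = ssd_ap / (P - 1)
            n1 = (n_t - sum(v**2 for v in n_p.values()) / n_t) / (P - 1)
            sig_a += (ms_ap - ms_wp) / n1
            sig_c += ms_wp
    return sig_a, sig_b, sig_c


def random_geno(rng, n_loci=3, n_ind=12, n_alleles=4, missing=0.1):
    catalogue = tuple(a + b for a in "ACGT" for b in "ACGT")[:n_alleles]
    loci = [MicrohapLocus(f"L{i}", f"c{i}", 2, catalogue) for i in range(n_loci)]
    calls = rng.integers(0, n_alleles, size=(n_loci, n_ind, 2)).astype(np.int32)
    miss = rng.random((n_loci, n_ind)) < missing
    calls[miss] = -1
    return GenotypeMatrix([f"i{k}" for k in range(n_ind)], loci, calls)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_single_level_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        geno = random_geno(rng)
        pops = [f"P{k % 3}" for k in range(12)]
        res = amova(geno, pops, n_perm=0, rng=rng)
        a, _, c = brute_force_components(geno, pops, None)
        assert res.table.loc[0, "sigma2"] == pytest.approx(a, abs=1e-12)
        assert res.table.loc[1, "sigma2"] == pytest.approx(c, abs=1e-12)
        assert res.f_statistics["F_ST"] == pytest.approx(a / (a + c), abs=1e-12)

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_hierarchical_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        geno = random_geno(rng, n_ind=16)
        pops = [f"P{k % 4}" for k in range(16)]
        groups = ["G1" if p in ("P0", "P1") else "G2" for p in pops]
        res = amova(geno, pops, groups=groups, n_perm=0, rng=rng)
        a, b, c = brute_force_components(geno, pops, groups)
        got = dict(zip(res.table["source"], res.table["sigma2"]))
        assert got["among_groups"] == pytest.approx(a, abs=1e-12)
        assert got["among_pops_within_groups"] == pytest.approx(b, abs=1e-12)
        assert got["within_pops"] == pytest.approx(c, abs=1e-12)
        tot = a + b + c
        assert res.f_statistics["F_CT"] == pytest.approx(a / tot, abs=1e-12)
        assert res.f_statistics["F_SC"] == pytest.approx(b / (b + c), abs=1e-12)
        assert res.f_statistics["F_ST"] == pytest.approx((a + b) / tot, abs=1e-12)


class TestStructure:
    def test_fixed_differences_give_fst_one(self):
        loci = [MicrohapLocus("L1", "c", 2, ("AA", "CC")),
                MicrohapLocus("L2", "c2", 2, ("GG", "TT"))]
        calls = np.array([
            [[0, 0]] * 3 + [[1, 1]] * 3,
            [[0, 0]] * 3 + [[1, 1]] * 3,
        ])
        geno = GenotypeMatrix([f"i{k}" for k in range(6)], loci, calls)
        res = amova(geno, ["A"] * 3 + ["B"] * 3, n_perm=49,
                    rng=np.random.default_rng(0))
        assert res.f_statistics["F_ST"] == pytest.approx(1.0, abs=1e-12)
        # 2 x (3!3!)/6! = 10% of label permutations reproduce the split, so
        # the smallest attainable p here is ~0.1
        assert res.p_values["F_ST"] <= 0.15

    def test_identical_populations_nonpositive_fst(self):
        loci = [MicrohapLocus("L1", "c", 2, ("AA", "CC"))]
        # both populations carry exactly one copy of each allele per individual
        calls = np.array([[[0, 1]] * 6])
        geno = GenotypeMatrix([f"i{k}" for k in range(6)], loci, calls)
        res = amova(geno, ["A"] * 3 + ["B"] * 3, n_perm=0,
                    rng=np.random.default_rng(0))
        assert res.f_statistics["F_ST"] <= 0
        assert res.has_negative_components

    def test_label_invariances(self):
        rng = np.random.default_rng(9)
        geno = random_geno(rng, missing=0.0)
        pops = [f"P{k % 3}" for k in range(12)]
        base = amova(geno, pops, n_perm=0, rng=rng)
        # permute individual order
        order = rng.permutation(12)
        geno2 = geno.subset(individual_idx=order)
        perm = amova(geno2, [pops[i] for i in order], n_perm=0, rng=rng)
        assert perm.f_statistics["F_ST"] == pytest.approx(
            base.f_statistics["F_ST"], abs=1e-12)
        # relabel alleles at one locus
        geno3 = geno.subset()
        remap = np.array([2, 3, 0, 1])
        geno3.calls[0] = remap[geno3.calls[0]]
        relab = amova(geno3, pops, n_perm=0, rng=rng)
        assert relab.f_statistics["F_ST"] == pytest.approx(
            base.f_statistics["F_ST"], abs=1e-12)

    def test_one_group_collapses_to_single_level(self):
        rng = np.random.default_rng(10)
        geno = random_geno(rng)
        pops = [f"P{k % 3}" for k in range(12)]
        single = amova(geno, pops, n_perm=0, rng=rng)
        with pytest.warns(UserWarning, match="single group"):
            collapsed = amova(geno, pops, groups=["G"] * 12, n_perm=0, rng=rng)
        assert collapsed.f_statistics["F_ST"] == pytest.approx(
            single.f_statistics["F_ST"], abs=1e-12)

    def test_percent_variation_sums_to_100(self):
        rng = np.random.default_rng(11)
        geno = random_geno(rng, n_ind=16)
        pops = [f"P{k % 4}" for k in range(16)]
        groups = ["G1" if p in ("P0", "P1") else "G2" for p in pops]
        res = amova(geno, pops, groups=groups, n_perm=0, rng=rng)
        assert res.table["percent_variation"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_population_rejected(self, toy_geno):
        toy_geno.calls[:, 2] = -1
        with pytest.raises(ValueError, match="zero observed gene copies"):
            amova(toy_geno, ["A", "A", "B"], n_perm=0,
                  rng=np.random.default_rng(0))


class TestPermutationNull:
    def test_p_uniform_under_null(self):
        # permutation p on label-shuffled data should be ~Uniform(0,1)
        from scipy.stats import kstest
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(150):
            geno = random_geno(rng, n_loci=4, n_ind=12, missing=0.0)
            pops = list(rng.permutation(["A"] * 6 + ["B"] * 6))
            res = amova(geno, pops, n_perm=49, rng=rng)
            pvals.append(res.p_values["F_ST"])
        stat = kstest(pvals, "uniform")
        assert stat.pvalue > 0.01


class TestPairwiseFst:
    def test_self_comparison_near_zero(self):
        rng = np.random.default_rng(13)
        geno = random_geno(rng, n_loci=40, n_ind=20, missing=0.0)
        # same panmictic pool split arbitrarily into two labels
        res = pairwise_fst(geno, ["A"] * 10 + ["B"] * 10, n_perm=49, rng=rng)
        assert abs(res.fst.loc["A", "B"]) < 0.05

    def test_island_model_recovery(self):
        # two demes at M = 9.5: expect F_ST ~ (d-1)/(Md+d-1) = 0.05
        rng = np.random.default_rng(14)
        geno, pops = island_genotypes(2, 30, 2, 9.5, 400, rng)
        res = amova(geno, pops, n_perm=0, rng=rng)
        assert res.f_statistics["F_ST"] == pytest.approx(0.05, abs=0.015)

    def test_per_locus_path_matches_amova(self):
        rng = np.random.default_rng(15)
        geno = random_geno(rng, n_loci=5, n_ind=12)
        pops = [f"P{k % 3}" for k in range(12)]
        res = amova(geno, pops, n_perm=0, rng=rng)
        tab = per_locus_fst(geno, pops)
        assert np.allclose(tab["fst_obs"].to_numpy(),
                           res.per_locus["fst"].to_numpy(), equal_nan=True)
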