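"""Locus-by-locus analysis of molecular variance (AMOVA) and pairwise F_ST.

Gene copies are the units of analysis; the distance between two copies is 0
if they carry the same microhaplotype allele and 1 otherwise, so the variance
components are on the heterozygosity scale and the resulting statistics are
F-statistics (not Phi-statistics).  Sums of squared deviations are
partitioned into among-groups / among-populations-within-groups /
within-populations per locus, variance components are recovered from the
mean squares with the classical unequal-sample-size coefficients, components
are summed over loci, and the F-statistics are formed as ratios of the
summed components.  Missing genotypes simply reduce the per-locus gene-copy
counts; degrees of freedom are computed per locus from the populations
actually observed there.  Negative variance components are retained in the
sums (not truncated to zero).

Significance is assessed by permutation, one scheme per statistic:
F_ST — individuals among populations; F_SC — individuals among populations
within their group; F_CT — whole populations among groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, MISSING, bh_adjust

__all__ = ["AmovaResult", "PairwiseFstMatrix", "amova", "pairwise_fst",
           "per_locus_fst"]


# ---------------------------------------------------------------------------
# long-format gene-copy arrays

class _CopyTable:
    """Observed gene copies of a genotype matrix in long format."""

    def __init__(self, geno: GenotypeMatrix):
        offsets = np.concatenate([[0], np.cumsum([l.n_alleles for l in geno.loci])])
        self.n_cols = int(offsets[-1])
        self.col_locus = np.repeat(np.arange(geno.n_loci),
                                   [l.n_alleles for l in geno.loci])
        inds, loci, cols = [], [], []
        for li in range(geno.n_loci):
            calls = geno.calls[li]
            obs = np.nonzero((calls != MISSING).all(axis=1))[0]
            for copy in range(2):
                inds.append(obs)
                loci.append(np.full(len(obs), li))
                cols.append(offsets[li] + calls[obs, copy])
        self.copy_ind = np.concatenate(inds)
        self.copy_locus = np.concatenate(loci)
        self.copy_col = np.concatenate(cols)
        self.n_loci = geno.n_loci


def _ssd_terms(counts: np.ndarray, n: np.ndarray) -> np.ndarray:
    """T(X) = (n^2 - sum_a c_a^2) / (2 n) per locus-by-unit cell, 0 if empty."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (n.astype(float) ** 2 - counts) / (2.0 * n)
    return np.where(n > 0, t, 0.0)


def _locus_components(ct: _CopyTable, pop_of_ind: np.ndarray,
                      group_of_pop: Optional[np.ndarray]):
    """Per-locus variance components (sigma_a, sigma_b, sigma_c) and SSD table.

    For a single-level design (``group_of_pop`` None) sigma_a is the
    among-population component and sigma_b is zero.
    """
    P = int(pop_of_ind.max()) + 1
    L = ct.n_loci
    pop_of_copy = pop_of_ind[ct.copy_ind]

    # per (locus, pop) gene-copy counts
    n_lp = np.bincount(ct.copy_locus * P + pop_of_copy, minlength=L * P).reshape(L, P)
    # per (column, pop) allele counts -> squared sums per (locus, pop)
    c_colpop = np.bincount(ct.copy_col * P + pop_of_copy,
                           minlength=ct.n_cols * P).reshape(ct.n_cols, P)
    sq = (c_colpop.astype(float) ** 2)
    sumsq_lp = np.zeros((L, P))
    np.add.at(sumsq_lp, ct.col_locus, sq)

    n_lt = n_lp.sum(axis=1)
    c_total = c_colpop.sum(axis=1).astype(float)
    sumsq_lt = np.zeros(L)
    np.add.at(sumsq_lt, ct.col_locus, c_total**2)

    T_lp = _ssd_terms(sumsq_lp, n_lp)
    T_lt = _ssd_terms(sumsq_lt, n_lt)
    nonempty_p = (n_lp > 0)
    P_l = nonempty_p.sum(axis=1)

    if group_of_pop is None:
        ssd_wp = T_lp.sum(axis=1)
        ssd_ap = T_lt - ssd_wp
        df_wp = n_lt - P_l
        df_ap = P_l - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            ms_wp = np.where(df_wp > 0, ssd_wp / df_wp, 0.0)
            ms_ap = np.where(df_ap > 0, ssd_ap / df_ap, np.nan)
            sum_np2 = (n_lp.astype(float) ** 2).sum(axis=1)
            n_prime = np.where(df_ap > 0, (n_lt - sum_np2 / np.maximum(n_lt, 1)) / np.maximum(df_ap, 1), np.nan)
            sigma_c = ms_wp
            sigma_a = np.where(n_prime > 0, (ms_ap - sigma_c) / n_prime, np.nan)
        ssd = {"among": ssd_ap, "within": ssd_wp}
        df = {"among": df_ap, "within": df_wp}
        return (sigma_a, np.zeros(L), sigma_c), ssd, df, n_lt

    G = int(group_of_pop.max()) + 1
    group_ind = np.zeros((P, G))
    group_ind[np.arange(P), group_of_pop] = 1.0
    n_lg = n_lp @ group_ind
    c_colgroup = c_colpop @ group_ind
    sumsq_lg = np.zeros((L, G))
    np.add.at(sumsq_lg, ct.col_locus, c_colgroup**2)
    T_lg = _ssd_terms(sumsq_lg, n_lg)
    G_l = (n_lg > 0).sum(axis=1)

    ssd_wp = T_lp.sum(axis=1)
    ssd_ap = T_lg.sum(axis=1) - ssd_wp
    ssd_ag = T_lt - T_lg.sum(axis=1)
    df_wp = n_lt - P_l
    df_ap = P_l - G_l
    df_ag = G_l - 1

    n_lp_f = n_lp.astype(float)
    n_lg_f = n_lg
    with np.errstate(divide="ignore", invalid="ignore"):
        # sum over groups of (sum_{p in g} n_p^2) / n_g
        sum_np2_per_group = (n_lp_f**2) @ group_ind
        ratio_pg = np.where(n_lg_f > 0, sum_np2_per_group / np.maximum(n_lg_f, 1), 0.0).sum(axis=1)
        sum_np2 = (n_lp_f**2).sum(axis=1)
        sum_ng2 = (n_lg_f**2).sum(axis=1)
        n1 = np.where(df_ap > 0, (n_lt - ratio_pg) / np.maximum(df_ap, 1), np.nan)
        n2 = np.where(df_ag > 0, (ratio_pg - sum_np2 / np.maximum(n_lt, 1)) / np.maximum(df_ag, 1), np.nan)
        n3 = np.where(df_ag > 0, (n_lt - sum_ng2 / np.maximum(n_lt, 1)) / np.maximum(df_ag, 1), np.nan)
        ms_wp = np.where(df_wp > 0, ssd_wp / df_wp, 0.0)
        ms_ap = np.where(df_ap > 0, ssd_ap / df_ap, np.nan)
        ms_ag = np.where(df_ag > 0, ssd_ag / df_ag, np.nan)
        sigma_c = ms_wp
        sigma_b = np.where(n1 > 0, (ms_ap - sigma_c) / n1, np.nan)
        sigma_a = np.where(n3 > 0, (ms_ag - sigma_c - n2 * sigma_b) / n3, np.nan)
    ssd = {"among_groups": ssd_ag, "among_pops": ssd_ap, "within": ssd_wp}
    df = {"among_groups": df_ag, "among_pops": df_ap, "within": df_wp}
    return (sigma_a, sigma_b, sigma_c), ssd, df, n_lt


def _f_stats(sigma: tuple[np.ndarray, np.ndarray, np.ndarray],
             hierarchical: bool) -> dict[str, float]:
    a = np.nansum(sigma[0])
    b = np.nansum(sigma[1])
    c = np.nansum(sigma[2])
    tot = a + b + c
    if hierarchical:
        return {
            "F_CT": a / tot,
            "F_SC": b / (b + c),
            "F_ST": (a + b) / tot,
        }
    return {"F_ST": a / tot}


@dataclass
class AmovaResult:
    design: str  # "hierarchical" or "single_level"
    table: pd.DataFrame  # source, SSD, df, MS, sigma2, percent_variation
    f_statistics: dict[str, float]
    p_values: dict[str, float]
    per_locus: pd.DataFrame
    n_permutations: int
    has_negative_components: bool


def _labels_to_codes(labels: Sequence, individuals: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels)
    if len(arr) != len(individuals):
        raise ValueError("assignment length != number of individuals")
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def amova(geno: GenotypeMatrix, populations: Sequence,
          groups: Optional[Sequence] = None, n_perm: int = 10000,
          rng: Optional[np.random.Generator] = None,
          locus_ids: bool = True) -> AmovaResult:
    """Hierarchical or single-level locus-by-locus AMOVA.

    ``populations`` (and optionally ``groups``) are labels aligned with
    ``geno.individuals``.  With groups present, the three-level design
    yields F_CT (among groups), F_SC (among populations within groups) and
    F_ST (among populations overall); otherwise the single-level design
    yields F_ST only.  Permutation p-values count permuted statistics >=
    observed, including the observed arrangement: (count + 1)/(n_perm + 1).
    """
    rng = np.random.default_rng() if rng is None else rng
    pop_of_ind = _labels_to_codes(populations, geno.individuals)
    P = pop_of_ind.max() + 1
    if P < 2:
        raise ValueError("need >= 2 populations")
    ct = _CopyTable(geno)
    # every population must contribute gene copies somewhere
    pop_copy_tot = np.bincount(pop_of_ind[ct.copy_ind], minlength=P)
    if (pop_copy_tot == 0).any():
        raise ValueError("a population has zero observed gene copies at every locus")

    hierarchical = groups is not None
    group_of_pop = None
    if hierarchical:
        grp_labels = np.asarray(groups)
        group_of_pop = np.empty(P, dtype=int)
        uniq_groups, grp_codes = np.unique(grp_labels, return_inverse=True)
        for p in range(P):
            gset = set(grp_codes[pop_of_ind == p])
            if len(gset) != 1:
                raise ValueError("a population spans two groups")
            group_of_pop[p] = gset.pop()
        if len(uniq_groups) < 2:
            # degenerate hierarchy: collapses to the single-level design
            import warnings
            warnings.warn("hierarchical design with a single group collapses "
                          "to single-level AMOVA")
            hierarchical = False
            group_of_pop = None

    sigma, ssd, df, n_lt = _locus_components(ct, pop_of_ind, group_of_pop)
    obs = _f_stats(sigma, hierarchical)

    # permutations
    counts_ge = {k: 0 for k in obs}
    group_of_ind = group_of_pop[pop_of_ind] if hierarchical else None
    for _ in range(n_perm):
        if hierarchical:
            # F_CT: permute whole populations among groups
            perm_gop = rng.permutation(group_of_pop)
            s_ct, _, _, _ = _locus_components(ct, pop_of_ind, perm_gop)
            if _f_stats(s_ct, True)["F_CT"] >= obs["F_CT"] - 1e-15:
                counts_ge["F_CT"] += 1
            # F_SC: permute individuals among populations within groups
            perm_pop = pop_of_ind.copy()
            for g in range(group_of_pop.max() + 1):
                idx = np.nonzero(group_of_ind == g)[0]
                perm_pop[idx] = pop_of_ind[idx][rng.permutation(len(idx))]
            s_sc, _, _, _ = _locus_components(ct, perm_pop, group_of_pop)
            if _f_stats(s_sc, True)["F_SC"] >= obs["F_SC"] - 1e-15:
                counts_ge["F_SC"] += 1
            # F_ST: permute individuals among populations (across groups)
            perm_pop = pop_of_ind[rng.permutation(len(pop_of_ind))]
            s_st, _, _, _ = _locus_components(ct, perm_pop, group_of_pop)
            if _f_stats(s_st, True)["F_ST"] >= obs["F_ST"] - 1e-15:
                counts_ge["F_ST"] += 1
        else:
            perm_pop = pop_of_ind[rng.permutation(len(pop_of_ind))]
            s_st, _, _, _ = _locus_components(ct, perm_pop, None)
            if _f_stats(s_st, False)["F_ST"] >= obs["F_ST"] - 1e-15:
                counts_ge["F_ST"] += 1
    p_values = {k: (counts_ge[k] + 1) / (n_perm + 1) for k in obs} if n_perm > 0 else {}

    # summary table on summed components
    sums = [np.nansum(sigma[0]), np.nansum(sigma[1]), np.nansum(sigma[2])]
    total = sum(sums)
    if hierarchical:
        sources = ["among_groups", "among_pops_within_groups", "within_pops"]
        ssd_keys = ["among_groups", "among_pops", "within"]
        comp = sums
    else:
        sources = ["among_pops", "within_pops"]
        ssd_keys = ["among", "within"]
        comp = [sums[0], sums[2]]
        total = sums[0] + sums[2]
    table = pd.DataFrame({
        "source": sources,
        "SSD": [float(np.nansum(ssd[k])) for k in ssd_keys],
        "df": [int(np.nansum(df[k])) for k in ssd_keys],
        "sigma2": comp,
        "percent_variation": [100.0 * c / total for c in comp],
    })

    per_locus = pd.DataFrame({
        "locus": np.arange(ct.n_loci),
        "n_copies": n_lt,
        "sigma_a": sigma[0],
        "sigma_b": sigma[1] if hierarchical else np.nan,
        "sigma_c": sigma[2],
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        tot_l = sigma[0] + sigma[1] + sigma[2]
        per_locus["fst"] = np.where(tot_l != 0,
                                    (sigma[0] + sigma[1]) / tot_l, np.nan)

    return AmovaResult(
        design="hierarchical" if hierarchical else "single_level",
        table=table,
        f_statistics=obs,
        p_values=p_values,
        per_locus=per_locus,
        n_permutations=n_perm,
        has_negative_components=bool(np.nanmin(comp) < 0),
    )


def per_locus_fst(geno: GenotypeMatrix, populations: Sequence) -> pd.DataFrame:
    """Per-locus single-level F_ST and within-population gene diversity.

    This is the shared code path the outlier scan uses: per-locus F_ST comes
    from the same AMOVA variance components; het is the unbiased
    within-population gene diversity averaged over the populations observed
    at the locus.
    """
    pop_of_ind = _labels_to_codes(populations, geno.individuals)
    P = pop_of_ind.max() + 1
    ct = _CopyTable(geno)
    sigma, _, _, n_lt = _locus_components(ct, pop_of_ind, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        tot = sigma[0] + sigma[2]
        fst = np.where(tot != 0, sigma[0] / tot, np.nan)
    # within-population unbiased gene diversity
    pop_of_copy = pop_of_ind[ct.copy_ind]
    L = ct.n_loci
    n_lp = np.bincount(ct.copy_locus * P + pop_of_copy, minlength=L * P).reshape(L, P)
    c_colpop = np.bincount(ct.copy_col * P + pop_of_copy,
                           minlength=ct.n_cols * P).reshape(ct.n_cols, P)
    sumsq_lp = np.zeros((L, P))
    np.add.at(sumsq_lp, ct.col_locus, c_colpop.astype(float) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_lp = np.where(n_lp > 1,
                        n_lp / np.maximum(n_lp - 1.0, 1)
                        * (1.0 - sumsq_lp / np.maximum(n_lp, 1) ** 2), np.nan)
    het = np.nanmean(np.where(n_lp > 1, h_lp, np.nan), axis=1)
    return pd.DataFrame({
        "locus_id": [l.locus_id for l in _loci_of(geno)],
        "fst_obs": fst,
        "het_obs": het,
        "n_copies": n_lt,
    })


def _loci_of(geno: GenotypeMatrix):
    return geno.loci


@dataclass
class PairwiseFstMatrix:
    groups: list[str]
    fst: pd.DataFrame
    p_raw: pd.DataFrame
    q_bh: pd.DataFrame


def pairwise_fst(geno: GenotypeMatrix, populations: Sequence,
                 n_perm: int = 10000,
                 rng: Optional[np.random.Generator] = None) -> PairwiseFstMatrix:
    """Pairwise F_ST between all population pairs, each via a two-population
    single-level AMOVA, permutation p-values, BH correction across pairs."""
    rng = np.random.default_rng() if rng is None else rng
    labels = np.asarray(populations)
    pops = list(pd.unique(labels))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    fst = pd.DataFrame(np.nan, index=pops, columns=pops)
    p_raw = pd.DataFrame(np.nan, index=pops, columns=pops)
    pairs = []
    for a, b in combinations(pops, 2):
        idx = np.nonzero((labels == a) | (labels == b))[0]
        sub = geno.subset(individual_idx=idx)
        res = amova(sub, labels[idx], n_perm=n_perm, rng=rng)
        f = res.f_statistics["F_ST"]
        p = res.p_values.get("F_ST", np.nan)
        fst.loc[a, b] = fst.loc[b, a] = f
        p_raw.loc[a, b] = p_raw.loc[b, a] = p
        pairs.append((a, b, p))
    qs = bh_adjust([p for _, _, p in pairs])
    q_bh = pd.DataFrame(np.nan, index=pops, columns=pops)
    for (a, b, _), q in zip(pairs, qs):
        q_bh.loc[a, b] = q_bh.loc[b, a] = q
    return PairwiseFstMatrix(groups=pops, fst=fst, p_raw=p_raw, q_bh=q_bh)
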