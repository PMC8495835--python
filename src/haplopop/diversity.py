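"""Per-group genomic diversity and its comparison framework.

Three per-locus measures are computed for each group of individuals
(typically an estuary): Nei's unbiased gene diversity H, the rarefied allele
count A_g (expected number of distinct alleles in a hypergeometric
down-sample of g gene copies), and E5 evenness — the ratio of the
Stoddart–Taylor index (1/lambda, weighting abundant alleles) and the
exponential Shannon–Wiener index (weighting rare alleles).  Heterogeneity
among groups is tested with a Friedman rank-sum test with loci as blocks,
followed by pairwise Wilcoxon signed-rank tests with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.special import gammaln

from .model import Dataset, GenotypeMatrix, MISSING, bh_adjust

__all__ = [
    "nei_gene_diversity", "rarefied_allele_count", "evenness_e5",
    "diversity_records", "fixed_allele_analysis", "compare_diversity",
    "FixedAlleleSets", "DiversityComparison",
]


def nei_gene_diversity(allele_counts: Sequence[int]) -> float:
    """Nei's unbiased gene diversity H = n/(n-1) * (1 - sum p_i^2)."""
    c = np.asarray(allele_counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("gene diversity needs >= 2 gene copies")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - (p**2).sum()))


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_allele_count(allele_counts: Sequence[int], g: int) -> float:
    """Expected allele count in a down-sample of g gene copies.

    E[A_g] = sum_i [ 1 - C(N - N_i, g) / C(N, g) ]  (hypergeometric rarefaction).
    """
    c = np.asarray(allele_counts, dtype=float)
    c = c[c > 0]
    N = c.sum()
    if not 1 <= g <= N:
        raise ValueError(f"rarefaction depth g={g} outside 1..{int(N)}")
    rest = N - c
    with np.errstate(divide="ignore"):
        term = np.where(rest >= g,
                        np.exp(_log_comb(rest, g) - _log_comb(np.array([N]), g)),
                        0.0)
    return float((1.0 - term).sum())


def evenness_e5(allele_counts: Sequence[float]) -> float:
    """E5 = (1/lambda - 1) / (exp(H') - 1); 1 for equifrequent alleles.

    A monomorphic locus is the 0/0 limit and returns 1 by convention so that
    distribution comparisons do not drop loci asymmetrically.
    """
    c = np.asarray(allele_counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("no observed alleles")
    p = c / c.sum()
    if p.size == 1:
        return 1.0
    lam = float((p**2).sum())
    h_shannon = float(-(p * np.log(p)).sum())
    return float((1.0 / lam - 1.0) / (np.exp(h_shannon) - 1.0))


def diversity_records(geno: GenotypeMatrix, populations: Sequence,
                      g: Optional[int] = None) -> pd.DataFrame:
    """Long-format per-(group, locus) diversity table.

    The rarefaction depth defaults, per locus, to the smallest per-group
    observed gene-copy count across the compared groups (reported in the
    ``g`` column).  Loci where any group has < 2 copies get NaN rows for the
    groups concerned.
    """
    labels = np.asarray(populations)
    groups = list(pd.unique(labels))
    rows = []
    for li, locus in enumerate(geno.loci):
        counts = {grp: geno.allele_counts(li, np.nonzero(labels == grp)[0])
                  for grp in groups}
        ns = {grp: int(c.sum()) for grp, c in counts.items()}
        min_n = min(ns.values())
        depth = g if g is not None else min_n
        for grp in groups:
            c = counts[grp]
            n = ns[grp]
            if n < 2 or depth < 1 or depth > n:
                rows.append((grp, locus.locus_id, np.nan, np.nan, np.nan, depth, n))
                continue
            rows.append((grp, locus.locus_id,
                         nei_gene_diversity(c),
                         rarefied_allele_count(c, depth),
                         evenness_e5(c), depth, n))
    return pd.DataFrame(rows, columns=["group", "locus_id", "H", "A_g", "E5",
                                       "g", "n_copies"])


@dataclass
class FixedAlleleSets:
    fixed_by_group: dict[str, set[str]]
    intersection_counts: pd.DataFrame  # one row per observed group-combination
    global_rarefied: pd.DataFrame      # locus_id, A_g over all individuals


def fixed_allele_analysis(geno: GenotypeMatrix, populations: Sequence,
                          g_global: int = 2) -> FixedAlleleSets:
    """Per-group fixed-locus sets and their exclusive (UpSet-style) intersections.

    A locus is fixed in a group when a single allele is observed there.  Each
    fixed locus is counted in exactly the combination of groups in which it
    is fixed.  For every locus fixed anywhere, the global rarefied allele
    count (over all individuals) is reported as a measure of how diverse the
    locus is elsewhere.
    """
    labels = np.asarray(populations)
    groups = list(pd.unique(labels))
    fixed: dict[str, set[str]] = {grp: set() for grp in groups}
    for li, locus in enumerate(geno.loci):
        for grp in groups:
            c = geno.allele_counts(li, np.nonzero(labels == grp)[0])
            if c.sum() >= 2 and (c > 0).sum() == 1:
                fixed[grp].add(locus.locus_id)
    combo_counts: dict[tuple[str, ...], int] = {}
    all_fixed = set().union(*fixed.values()) if fixed else set()
    for locus_id in all_fixed:
        combo = tuple(sorted(grp for grp in groups if locus_id in fixed[grp]))
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
    inter = pd.DataFrame(
        [(";".join(combo), len(combo), cnt)
         for combo, cnt in sorted(combo_counts.items(), key=lambda kv: -kv[1])],
        columns=["groups", "degree", "count"],
    )
    lid_index = geno.locus_index()
    glob = []
    for locus_id in sorted(all_fixed):
        c = geno.allele_counts(lid_index[locus_id])
        depth = min(g_global, int(c.sum()))
        glob.append((locus_id, rarefied_allele_count(c, depth) if c.sum() >= 1 else np.nan))
    return FixedAlleleSets(
        fixed_by_group=fixed,
        intersection_counts=inter,
        global_rarefied=pd.DataFrame(glob, columns=["locus_id", "A_g_global"]),
    )


def _friedman_two_treatments(data: np.ndarray) -> tuple[float, float]:
    """Friedman rank statistic for k = 2 treatments (tie-corrected).

    scipy's implementation requires k >= 3; for two groups the same rank
    formula reduces to a sign-test-like chi-square on 1 df.
    """
    n, k = data.shape
    ranks = sp_stats.rankdata(data, axis=1)
    ssbn = (ranks.sum(axis=0) ** 2).sum()
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += ((counts**3) - counts).sum()
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c == 0.0:
        return 0.0, 1.0
    Q = (12.0 / (n * k * (k + 1)) * ssbn - 3 * n * (k + 1)) / c
    return float(Q), float(sp_stats.chi2.sf(Q, k - 1))


@dataclass
class DiversityComparison:
    metric: str
    friedman_Q: float
    friedman_df: int
    friedman_p: float
    pairwise: pd.DataFrame  # group_a, group_b, p_raw, q_bh
    n_blocks: int
    n_dropped_blocks: int


def compare_diversity(records: pd.DataFrame, metric: str = "H") -> DiversityComparison:
    """Friedman test (loci = blocks, groups = treatments) + pairwise Wilcoxon.

    Loci not observed in every group (incomplete blocks) are dropped and
    counted.
    """
    wide = records.pivot_table(index="locus_id", columns="group", values=metric,
                               aggfunc="first")
    n_total = wide.shape[0]
    wide = wide.dropna()
    n_blocks = wide.shape[0]
    if wide.shape[1] < 2 or n_blocks < 2:
        raise ValueError("need >= 2 groups and >= 2 complete blocks")
    cols = [wide[c].to_numpy() for c in wide.columns]
    if len(cols) >= 3:
        Q, p = sp_stats.friedmanchisquare(*cols)
    else:
        Q, p = _friedman_two_treatments(np.column_stack(cols))
    rows = []
    for a, b in combinations(wide.columns, 2):
        diff = wide[a].to_numpy() - wide[b].to_numpy()
        if np.all(diff == 0):
            pw = 1.0
        else:
            pw = float(sp_stats.wilcoxon(wide[a], wide[b], zero_method="wilcox").pvalue)
        rows.append((a, b, pw))
    pair = pd.DataFrame(rows, columns=["group_a", "group_b", "p_raw"])
    pair["q_bh"] = bh_adjust(pair["p_raw"].to_numpy())
    return DiversityComparison(
        metric=metric, friedman_Q=float(Q), friedman_df=wide.shape[1] - 1,
        friedman_p=float(p), pairwise=pair, n_blocks=n_blocks,
        n_dropped_blocks=n_total - n_blocks,
    )
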