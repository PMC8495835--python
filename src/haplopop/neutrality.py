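"""Per-locus sequence statistics and neutrality tests.

For each microhaplotype locus within a group of individuals we compute the
number of segregating sites S, the mean pairwise difference k̂, the two
theta estimators (Watterson's Θ_W = S/a1 from segregating sites, and
nucleotide diversity Θ_T = k̂ from pairwise differences), and Tajima's D —
the normalized difference between the two.  Under drift–mutation equilibrium
E[D] ≈ 0; a genome-wide shift towards negative D signals population
expansion, while locus-specific extremes suggest selection.

Two tests are provided: the classical beta-approximation test for a single
locus (Tajima 1989's confidence-limit construction), and a genome-wide test
that compares the observed mean/median of D against replicate null genomes
simulated from the constant-size coalescent conditioned on the observed
per-locus sample sizes and segregating-site counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.special import betainc

from .model import Dataset, MISSING, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "TajimaConstants",
    "LocusNeutralityStats",
    "GenomeWideDTest",
    "tajima_constants",
    "harmonic",
    "locus_stats",
    "locus_stats_from_sites",
    "tajima_test_beta",
    "dataset_locus_stats",
    "genome_wide_null_test",
    "compare_theta",
    "significance_summary",
]


def harmonic(m: int, power: int = 1) -> float:
    """sum_{i=1}^{m} 1/i**power."""
    i = np.arange(1, m + 1, dtype=float)
    return float((1.0 / i**power).sum())


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=4096)
def tajima_constants(n: int) -> TajimaConstants:
    """The Tajima (1989) normalizing constants for n gene copies (n >= 4)."""
    if n < 4:
        raise ValueError("Tajima variance constants need n >= 4")
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class LocusNeutralityStats:
    locus_id: str
    group: str
    n: int
    S: int
    k_hat: float
    theta_W: float
    theta_T: float
    D: float  # NaN when undefined (S = 0 or n < 4)
    p_beta: float = np.nan
    length_bp: Optional[int] = None

    @property
    def theta_W_per_site(self) -> float:
        return self.theta_W / self.length_bp if self.length_bp else np.nan

    @property
    def theta_T_per_site(self) -> float:
        return self.theta_T / self.length_bp if self.length_bp else np.nan

    @property
    def sign(self) -> str:
        if not np.isfinite(self.D):
            return "undefined"
        return "positive" if self.D > 0 else "negative"


def _stats_from_site_allele_counts(site_counts: list[np.ndarray], n: int) -> tuple[int, float]:
    """(S, k_hat) from per-site allele-count vectors over n gene copies."""
    S = 0
    diff_pairs = 0.0
    pairs = n * (n - 1) / 2.0
    for counts in site_counts:
        counts = counts[counts > 0]
        if len(counts) >= 2:
            S += 1
            diff_pairs += pairs - (counts * (counts - 1) / 2.0).sum()
    return S, float(diff_pairs / pairs) if pairs > 0 else np.nan


def _assemble(locus_id: str, group: str, n: int, S: int, k_hat: float,
              length_bp: Optional[int]) -> LocusNeutralityStats:
    a1 = harmonic(n - 1) if n >= 2 else np.nan
    theta_W = S / a1 if n >= 2 else np.nan
    D = np.nan
    p = np.nan
    if S > 0 and n >= 4:
        const = tajima_constants(n)
        denom = np.sqrt(const.e1 * S + const.e2 * S * (S - 1))
        D = float((k_hat - S / const.a1) / denom)
        p = tajima_test_beta(D, n)
    return LocusNeutralityStats(
        locus_id=locus_id, group=group, n=n, S=S, k_hat=k_hat,
        theta_W=float(theta_W), theta_T=float(k_hat), D=D, p_beta=p,
        length_bp=length_bp,
    )


def locus_stats(haplotypes: Sequence[str], locus_id: str = "", group: str = "",
                length_bp: Optional[int] = None) -> LocusNeutralityStats:
    """Statistics for one locus from its n aligned gene-copy strings."""
    n = len(haplotypes)
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    lens = {len(h) for h in haplotypes}
    if len(lens) != 1:
        raise ValueError("haplotype strings of unequal length")
    arr = np.frombuffer("".join(haplotypes).encode(), dtype="S1").reshape(n, -1)
    site_counts = []
    for j in range(arr.shape[1]):
        _, counts = np.unique(arr[:, j], return_counts=True)
        site_counts.append(counts.astype(float))
    S, k_hat = _stats_from_site_allele_counts(site_counts, n)
    if length_bp is None:
        length_bp = arr.shape[1]
    return _assemble(locus_id, group, n, S, k_hat, length_bp)


def locus_stats_from_sites(site_matrix: np.ndarray, locus_id: str = "",
                           group: str = "", length_bp: Optional[int] = None
                           ) -> LocusNeutralityStats:
    """Statistics from an n x S binary derived-allele matrix."""
    site_matrix = np.asarray(site_matrix)
    n = site_matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    site_counts = []
    for j in range(site_matrix.shape[1]):
        c = site_matrix[:, j].sum()
        site_counts.append(np.array([n - c, c], dtype=float))
    S, k_hat = _stats_from_site_allele_counts(site_counts, n)
    return _assemble(locus_id, group, n, S, k_hat, length_bp)


def tajima_test_beta(D: float, n: int) -> float:
    """Two-sided p-value for Tajima's D under the beta approximation.

    The null density of D is approximated by a beta law rescaled to the
    attainable range [Dmin, Dmax], with shape parameters chosen so the
    distribution has mean 0 and variance 1.
    """
    if not np.isfinite(D):
        raise ValueError("D must be defined")
    const = tajima_constants(n)
    sqrt_e2 = np.sqrt(const.e2)
    Dmin = (2.0 / n - 1.0 / const.a1) / sqrt_e2
    Dmax = ((n + 1) / (2.0 * n) - 1.0 / const.a1) / sqrt_e2
    if D < Dmin - 1e-9 or D > Dmax + 1e-9:
        warnings.warn(f"D={D:.4f} outside attainable range [{Dmin:.4f}, {Dmax:.4f}]; clamped")
    D = min(max(D, Dmin), Dmax)
    tmp1 = 1.0 + Dmin * Dmax
    tmp2 = Dmax - Dmin
    a = -tmp1 * Dmax / tmp2
    b = tmp1 * Dmin / tmp2
    x = (D - Dmin) / tmp2
    p = float(betainc(b, a, x))
    return 2.0 * p if p < 0.5 else 2.0 * (1.0 - p)


def dataset_locus_stats(ds: Dataset, group_by: str = "estuary",
                        min_copies: int = 4) -> list[LocusNeutralityStats]:
    """Per-locus stats with individuals grouped by estuary (or basin).

    The per-group sample size n is the observed (missingness-reduced)
    gene-copy count at that locus.  Groups with fewer than ``min_copies``
    copies at a locus are skipped there.
    """
    labels = ds.estuary_of() if group_by == "estuary" else ds.basin_of()
    geno = ds.genotypes
    out: list[LocusNeutralityStats] = []
    for group in pd.unique(labels):
        idx = np.nonzero(labels == group)[0]
        for li, locus in enumerate(geno.loci):
            calls = geno.calls[li, idx]
            obs = calls[(calls != MISSING).all(axis=1)]
            n = 2 * len(obs)
            if n < min_copies:
                continue
            haps = [locus.alleles[a] for a in obs.ravel()]
            out.append(locus_stats(haps, locus_id=locus.locus_id, group=str(group),
                                   length_bp=locus.length_bp))
    return out


def stats_to_frame(stats: Sequence[LocusNeutralityStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.locus_id, s.group, s.n, s.S, s.k_hat, s.theta_W, s.theta_T,
          s.theta_W_per_site, s.theta_T_per_site, s.D, s.p_beta)
         for s in stats],
        columns=["locus_id", "group", "n", "S", "k_hat", "theta_W", "theta_T",
                 "theta_W_per_site", "theta_T_per_site", "D", "p_beta"],
    )


@dataclass
class GenomeWideDTest:
    group: str
    observed_mean: float
    observed_median: float
    replicate_means: np.ndarray
    replicate_medians: np.ndarray
    p_mean_lower: float
    p_mean_upper: float
    p_median_lower: float
    p_median_upper: float
    n_loci: int
    R: int


def genome_wide_null_test(stats: Sequence[LocusNeutralityStats], R: int = 1000,
                          rng: Optional[np.random.Generator] = None,
                          group: str = "", plus_one: bool = False) -> GenomeWideDTest:
    """Genome-wide test of Tajima's D against matched coalescent nulls.

    For each of R replicates, every observed locus (with S > 0) is matched by
    one constant-size neutral coalescent locus with the same gene-copy count
    and exactly the same number of segregating sites; the replicate's mean and
    median D across loci form the null distribution for the observed mean and
    median.  p_mean_lower is the proportion of replicates whose mean is <=
    the observed mean (population expansion shifts the observed mean down, so
    small p_mean_lower is the expansion-consistent signal).

    With ``plus_one`` the (1 + count) / (R + 1) convention is used instead of
    the raw proportion.
    """
    from .coalescent import sim_tajima_d

    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    usable = [s for s in stats if s.S > 0 and s.n >= 4 and np.isfinite(s.D)]
    dropped = len(stats) - len(usable)
    if dropped:
        logger.info("genome_wide_null_test: %d loci without defined D excluded", dropped)
    if not usable:
        raise ValueError("no locus with S > 0")
    obs_D = np.array([s.D for s in usable])
    obs_mean = float(obs_D.mean())
    obs_median = float(np.median(obs_D))
    rep_means = np.empty(R)
    rep_medians = np.empty(R)
    for r in range(R):
        sim_D = np.array([sim_tajima_d(s.n, s.S, rng) for s in usable])
        rep_means[r] = sim_D.mean()
        rep_medians[r] = np.median(sim_D)

    def prop(count: int) -> float:
        return (1 + count) / (R + 1) if plus_one else count / R

    return GenomeWideDTest(
        group=group,
        observed_mean=obs_mean,
        observed_median=obs_median,
        replicate_means=rep_means,
        replicate_medians=rep_medians,
        p_mean_lower=prop(int((rep_means <= obs_mean).sum())),
        p_mean_upper=prop(int((rep_means >= obs_mean).sum())),
        p_median_lower=prop(int((rep_medians <= obs_median).sum())),
        p_median_upper=prop(int((rep_medians >= obs_median).sum())),
        n_loci=len(usable),
        R=R,
    )


def compare_theta(groups: dict[str, Sequence[LocusNeutralityStats]],
                  estimator: str = "theta_W", per_site: bool = False) -> pd.DataFrame:
    """Pairwise Mann–Whitney tests on per-locus theta values, BH-adjusted."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    values: dict[str, np.ndarray] = {}
    for g, stats in groups.items():
        if per_site:
            v = np.array([getattr(s, estimator + "_per_site") for s in stats])
        else:
            v = np.array([getattr(s, estimator) for s in stats])
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"group {g}: fewer than 2 loci")
        values[g] = v
    rows = []
    for a, b in combinations(values, 2):
        va, vb = values[a], values[b]
        if len(va) == len(vb) and np.array_equal(np.sort(va), np.sort(vb)):
            warnings.warn(f"compare_theta: identical value multisets for {a} vs {b}")
            p = 1.0
        else:
            p = float(sp_stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        rows.append((a, b, float(np.mean(va)), float(np.mean(vb)), p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_a", "mean_b", "p_raw"])
    df["q_bh"] = bh_adjust(df["p_raw"].to_numpy())
    return df


def significance_summary(stats: Sequence[LocusNeutralityStats],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Count loci with significant positive/negative D in at least one group.

    BH correction is applied within each group (estuary) separately; counts
    are reported before and after correction.
    """
    df = stats_to_frame(list(stats)).dropna(subset=["D", "p_beta"])
    df = df.copy()
    df["q_beta"] = np.nan
    for g, sub in df.groupby("group"):
        df.loc[sub.index, "q_beta"] = bh_adjust(sub["p_beta"].to_numpy())
    rows = []
    for label, col in (("raw", "p_beta"), ("bh", "q_beta")):
        sig = df[df[col] < alpha]
        pos = set(sig.loc[sig["D"] > 0, "locus_id"])
        neg = set(sig.loc[sig["D"] < 0, "locus_id"])
        rows.append((label, len(pos | neg), len(pos - neg), len(neg - pos),
                     len(pos & neg)))
    return pd.DataFrame(rows, columns=["correction", "any", "positive_only",
                                       "negative_only", "both_signs"])
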