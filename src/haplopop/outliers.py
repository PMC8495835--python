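"""fdist-style F_ST outlier scan under a strict island model.

The scan asks, for every locus, whether its F_ST is higher than expected for
a neutral locus of comparable heterozygosity.  The neutral expectation is
built by coalescent simulation of a finite island model whose migration rate
is calibrated so the mean simulated F_ST matches the observed genome-wide
value; simulated loci are infinite-sites haplotypes collapsed to allele
identities, exactly how the observed multiallelic microhaplotypes are
treated.  The empirical p-value of a locus is the proportion of simulated
loci with F_ST at least as large, among simulated loci in the same
heterozygosity stratum (equal-count bins).  Only the high tail is tested
(directional-selection candidates); loci putatively under balancing
selection are not assessed.

A consensus partition step intersects the scan's flags with an externally
supplied second flag list (e.g. from a Bayesian method) and calls everything
else neutral.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amova import _CopyTable, per_locus_fst
from .coalescent import sim_island_locus
from .model import GenotypeMatrix, bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["OutlierScan", "LocusPartition", "calibrate_migration",
           "fdist_scan", "partition_loci"]

_M_CAP = 1e4


def _sim_fst_het(labels: np.ndarray, deme_of_sample: np.ndarray) -> tuple[float, float, float, float]:
    """(sigma_a, sigma_total, het, n) for one simulated locus from allele labels."""
    pops = np.unique(deme_of_sample)
    A = labels.max() + 1
    counts = np.zeros((len(pops), A))
    for i, p in enumerate(pops):
        c = np.bincount(labels[deme_of_sample == p], minlength=A)
        counts[i] = c
    n_p = counts.sum(axis=1)
    T_p = (n_p**2 - (counts**2).sum(axis=1)) / (2.0 * n_p)
    tot = counts.sum(axis=0)
    n_t = n_p.sum()
    T_t = (n_t**2 - (tot**2).sum()) / (2.0 * n_t)
    P = len(pops)
    ssd_a = T_t - T_p.sum()
    ssd_w = T_p.sum()
    ms_w = ssd_w / (n_t - P)
    ms_a = ssd_a / (P - 1)
    n_prime = (n_t - (n_p**2).sum() / n_t) / (P - 1)
    sigma_a = (ms_a - ms_w) / n_prime
    het = float(np.mean(n_p / (n_p - 1.0) * (1.0 - (counts / n_p[:, None]) ** 2
                                             @ np.ones(A))))
    return float(sigma_a), float(sigma_a + ms_w), het, float(n_t)


def _simulate_batch(n_loci: int, sample_sizes: Sequence[int], d_sim: int,
                    M: float, theta_range: tuple[float, float],
                    rng: np.random.Generator,
                    max_attempts_factor: int = 20) -> pd.DataFrame:
    """Simulate island-model loci until n_loci polymorphic ones are collected."""
    lo, hi = theta_range
    rows = []
    attempts = 0
    while len(rows) < n_loci:
        attempts += 1
        if attempts > max_attempts_factor * n_loci:
            raise RuntimeError("island-model simulation: too many monomorphic loci")
        theta = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        loc = sim_island_locus(sample_sizes, d_demes=d_sim, M=M, theta=theta, rng=rng)
        if loc.S == 0:
            continue
        labels = loc.haplotype_labels()
        if labels.max() == 0:
            continue
        sigma_a, sigma_t, het, _ = _sim_fst_het(labels, loc.deme_of_sample)
        rows.append((sigma_a, sigma_t, sigma_a / sigma_t if sigma_t != 0 else np.nan, het))
    return pd.DataFrame(rows, columns=["sigma_a", "sigma_t", "fst", "het"])


def _mean_fst(batch: pd.DataFrame) -> float:
    """Ratio-of-sums mean F_ST over a batch of simulated loci."""
    return float(batch["sigma_a"].sum() / batch["sigma_t"].sum())


def calibrate_migration(target_fst: float, d_sim: int,
                        sample_sizes: Sequence[int],
                        rng: Optional[np.random.Generator] = None,
                        pilot_loci: int = 2000,
                        theta_range: tuple[float, float] = (0.1, 5.0),
                        tol: float = 0.005, max_steps: int = 30) -> float:
    """Scaled migration rate M such that simulated mean F_ST matches target.

    Initialized at the island-model closed form for the AMOVA-style
    estimator, M = (1/F - 1) * (d - 1)/d (from F = (T_b - T_w)/T_b with
    T_w = d and T_b - T_w = (d - 1)/M), and refined by bisection on
    simulated batch means (ratio of summed variance components).
    """
    if not 0.0 < target_fst < 1.0:
        raise ValueError("target_fst must be in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    M0 = (1.0 / target_fst - 1.0) * (d_sim - 1) / d_sim
    if M0 > _M_CAP:
        raise RuntimeError(f"calibration target {target_fst} needs M > cap {_M_CAP}")

    def mean_at(M: float) -> float:
        return _mean_fst(_simulate_batch(pilot_loci, sample_sizes, d_sim, M,
                                         theta_range, rng))

    f0 = mean_at(M0)
    if abs(f0 - target_fst) <= tol:
        return M0
    # mean F_ST decreases in M; expand to a bracket then bisect on log M
    lo_M, hi_M = M0, M0
    f_lo, f_hi = f0, f0
    steps = 0
    while f_lo < target_fst:  # need smaller M
        lo_M /= 2.0
        f_lo = mean_at(lo_M)
        steps += 1
        if steps > max_steps:
            raise RuntimeError("calibration failed to bracket target (low side)")
    while f_hi > target_fst:
        hi_M = min(hi_M * 2.0, _M_CAP)
        f_hi = mean_at(hi_M)
        steps += 1
        if hi_M >= _M_CAP and f_hi > target_fst:
            raise RuntimeError("calibration hit migration cap")
        if steps > max_steps:
            raise RuntimeError("calibration failed to bracket target (high side)")
    for _ in range(max_steps - steps):
        mid = float(np.sqrt(lo_M * hi_M))
        f_mid = mean_at(mid)
        if abs(f_mid - target_fst) <= tol:
            return mid
        if f_mid > target_fst:
            lo_M = mid
        else:
            hi_M = mid
    raise RuntimeError(
        f"calibration did not converge in {max_steps} steps "
        f"(bracket [{lo_M:.3g}, {hi_M:.3g}], target {target_fst})"
    )


@dataclass
class OutlierScan:
    table: pd.DataFrame  # locus_id, fst_obs, het_obs, p_high, q_bh, flagged
    metadata: dict


def fdist_scan(geno: GenotypeMatrix, populations: Sequence,
               n_sims: int = 20000, d_sim: int = 100, n_bins: int = 20,
               q_threshold: float = 0.05, pilot_loci: int = 2000,
               rng: Optional[np.random.Generator] = None,
               target_fst: Optional[float] = None) -> OutlierScan:
    """F_ST outlier scan against a calibrated island-model null."""
    rng = np.random.default_rng() if rng is None else rng
    obs = per_locus_fst(geno, populations)
    usable = obs.dropna(subset=["fst_obs", "het_obs"]).reset_index(drop=True)
    labels = np.asarray(populations)
    pops = pd.unique(labels)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    if target_fst is None:
        from .amova import amova
        res = amova(geno, populations, n_perm=0, rng=rng)
        target_fst = res.f_statistics["F_ST"]
    target_fst = float(np.clip(target_fst, 1e-4, 0.99))

    # matched sampling configuration: mean observed gene copies per population
    ct = _CopyTable(geno)
    pop_codes = pd.Series(labels).astype("category").cat.codes.to_numpy()
    copies_per_pop = np.bincount(pop_codes[ct.copy_ind], minlength=len(pops))
    sample_sizes = np.maximum(2, np.round(copies_per_pop / geno.n_loci)).astype(int)

    # theta range spanning observed heterozygosities; within-deme pairwise
    # coalescence time in a d-deme island model is d (total size), so
    # E[het] ~ theta*d/(1 + theta*d) and theta ~ H/((1-H)*d)
    h = usable["het_obs"].clip(1e-4, 0.99)
    th = h / ((1.0 - h) * d_sim)
    theta_range = (max(float(th.min()) * 0.5, 1e-4), min(float(th.max()) * 2.0, 50.0))

    M = calibrate_migration(target_fst, d_sim, sample_sizes, rng=rng,
                            pilot_loci=pilot_loci, theta_range=theta_range)
    sims = _simulate_batch(n_sims, sample_sizes, d_sim, M, theta_range, rng)

    # equal-count heterozygosity strata
    n_bins_eff = n_bins
    while n_bins_eff > 1 and n_sims // n_bins_eff < 100:
        n_bins_eff -= 1
    if n_bins_eff != n_bins:
        warnings.warn(f"het strata widened from {n_bins} to {n_bins_eff} bins "
                      "to keep >= 100 simulated loci per stratum")
    edges = np.quantile(sims["het"], np.linspace(0, 1, n_bins_eff + 1)[1:-1])
    sim_bin = np.searchsorted(edges, sims["het"].to_numpy())
    obs_bin = np.searchsorted(edges, usable["het_obs"].to_numpy())
    sim_f = sims["fst"].to_numpy()
    p_high = np.empty(len(usable))
    for b in range(n_bins_eff):
        in_bin = sim_bin == b
        f_bin = np.sort(sim_f[in_bin])
        sel = obs_bin == b
        # P(F_sim >= F_obs) within stratum
        p_high[sel] = 1.0 - np.searchsorted(f_bin, usable.loc[sel, "fst_obs"],
                                            side="left") / len(f_bin)
    q = bh_adjust(p_high)
    table = usable.copy()
    table["p_high"] = p_high
    table["q_bh"] = q
    table["flagged"] = q < q_threshold
    meta = {
        "target_fst": target_fst, "M": M, "d_sim": d_sim, "n_sims": n_sims,
        "n_bins": n_bins_eff, "theta_range": theta_range,
        "sample_sizes": sample_sizes.tolist(), "q_threshold": q_threshold,
    }
    return OutlierScan(table=table, metadata=meta)


@dataclass
class LocusPartition:
    outlier_set: set[str]
    neutral_set: set[str]


def partition_loci(analyzed: Sequence[str], scan_a: set[str],
                   scan_b: Optional[set[str]] = None) -> LocusPartition:
    """Consensus partition: outliers = loci flagged by both methods.

    ``scan_b`` is an externally supplied flag list (one locus per line file,
    already parsed); with none supplied the partition is conservative — the
    outlier set is empty and every locus is treated as neutral.
    """
    analyzed_set = set(analyzed)
    if scan_b is None:
        scan_b = set()
    if not set(scan_a) <= analyzed_set or not set(scan_b) <= analyzed_set:
        raise ValueError("flag lists must be subsets of the analyzed loci")
    outliers = set(scan_a) & set(scan_b)
    return LocusPartition(outlier_set=outliers, neutral_set=analyzed_set - outliers)
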