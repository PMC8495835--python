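"""Hudson-style coalescent simulator.

Backbone for the neutrality null tests, the fdist-style outlier scan, and the
synthetic-data generator.  Supports a single deme of constant size or with
exponential growth, and structured models (finite island or an arbitrary
migration-rate matrix, e.g. stepping stones), with mutations dropped either
as an exact number of segregating sites (fixed-S) or at rate theta (Poisson
on total branch length).

Conventions
-----------
* Time is measured in units of 2N generations (N = deme size); the pairwise
  coalescence rate within a deme is 1 at time 0.
* ``M`` is the scaled migration rate 4Nm; each lineage migrates at total rate
  M/2.  A matrix entry ``M[i, j]`` is the scaled rate from deme i to deme j
  (backwards in time), per-lineage rate M[i, j]/2.
* ``alpha`` is the exponential growth rate in these units: looking backwards,
  deme size shrinks as N(t) = N(0) * exp(-alpha * t), so the coalescence
  intensity at time t is exp(alpha * t).
* Under the infinite-sites model every mutation is a new segregating site;
  sites on branches below the root carry 1..n-1 derived copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "CoalescentParams",
    "Genealogy",
    "SimulatedLocus",
    "sim_genealogy",
    "drop_mutations",
    "sim_island_locus",
    "sim_tajima_d",
]

MAX_EVENTS_DEFAULT = 10_000_000


@dataclass(frozen=True)
class CoalescentParams:
    """Bundle of simulation parameters (convenience for config plumbing)."""

    n_samples: Union[int, tuple[int, ...]]
    d_demes: int = 1
    M: float = 0.0
    alpha: float = 0.0
    S: Optional[int] = None
    theta: Optional[float] = None
    seed: Optional[int] = None


@dataclass
class Genealogy:
    """A realized coalescent tree, stored as its branches.

    Each branch is the interval a lineage existed for, together with the set
    of sampled leaves below it (a bitmask over sample indices).  The root
    lineage carries no branch.
    """

    n: int
    branch_masks: list[int]
    branch_lengths: np.ndarray
    deme_of_sample: np.ndarray
    t_mrca: float

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())


@dataclass
class SimulatedLocus:
    """Mutations dropped on a genealogy: an n x S derived-allele matrix."""

    site_matrix: np.ndarray  # (n, S) uint8, 1 = derived
    deme_of_sample: np.ndarray
    total_branch_length: float
    S: int

    def carrier_counts(self) -> np.ndarray:
        return self.site_matrix.sum(axis=0).astype(np.int64)

    def haplotype_labels(self) -> np.ndarray:
        """Collapse rows to allele identities (0-based, order of first appearance)."""
        n = self.site_matrix.shape[0]
        labels = np.empty(n, dtype=np.int64)
        seen: dict[bytes, int] = {}
        for i in range(n):
            key = self.site_matrix[i].tobytes()
            labels[i] = seen.setdefault(key, len(seen))
        return labels


def _next_coal_increment(C: float, alpha: float, t: float, rng: np.random.Generator) -> float:
    """Waiting time to next coalescence with intensity C * exp(alpha * (t + s))."""
    if C <= 0:
        return math.inf
    E = -math.log(1.0 - rng.random())
    if alpha == 0.0:
        return E / C
    arg = alpha * E * math.exp(-alpha * t) / C
    if arg <= -1.0:  # declining population that never coalesces
        return math.inf
    return math.log1p(arg) / alpha


def sim_genealogy(
    sample_sizes: Union[int, Sequence[int]],
    migration: Union[float, np.ndarray, None] = None,
    alpha: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    max_events: int = MAX_EVENTS_DEFAULT,
) -> Genealogy:
    """Simulate one genealogy under the (structured) coalescent.

    Parameters
    ----------
    sample_sizes : int or sequence of int
        Gene copies sampled, total (single deme) or per deme.
    migration : float or (d, d) array, optional
        Scalar M = 4Nm for a symmetric island model (destination uniform among
        the other demes), or a full scaled-rate matrix.  Ignored for d = 1.
    alpha : float
        Exponential growth rate (all demes), in 2N-generation units.
    """
    rng = np.random.default_rng() if rng is None else rng
    if isinstance(sample_sizes, (int, np.integer)):
        per_deme = [int(sample_sizes)]
    else:
        per_deme = [int(x) for x in sample_sizes]
    d = len(per_deme)
    n = sum(per_deme)
    if n < 2:
        raise ValueError("need at least 2 gene copies")

    # per-lineage out-rates and destination distributions
    if d > 1:
        if migration is None:
            mig_matrix = np.zeros((d, d))
        elif np.isscalar(migration):
            M = float(migration)
            mig_matrix = np.full((d, d), (M / 2.0) / (d - 1))
            np.fill_diagonal(mig_matrix, 0.0)
        else:
            mig_matrix = np.asarray(migration, dtype=float) / 2.0
            if mig_matrix.shape != (d, d):
                raise ValueError("migration matrix shape mismatch")
            mig_matrix = mig_matrix.copy()
            np.fill_diagonal(mig_matrix, 0.0)
        out_rate = mig_matrix.sum(axis=1)
    else:
        mig_matrix = np.zeros((1, 1))
        out_rate = np.zeros(1)

    deme_of_sample = np.repeat(np.arange(d), per_deme)

    # destination CDF per source deme, precomputed once
    if d > 1:
        with np.errstate(invalid="ignore"):
            dest_cdf = np.cumsum(mig_matrix, axis=1)
            dest_cdf = dest_cdf / np.where(out_rate[:, None] > 0,
                                           out_rate[:, None], 1.0)
    out_rate_l = out_rate.tolist()

    # active lineages: parallel lists, plus per-deme index lists for O(1) picks
    masks: list[int] = [1 << i for i in range(n)]
    births: list[float] = [0.0] * n
    by_deme: list[list[int]] = [[] for _ in range(d)]
    for lid, dm in enumerate(deme_of_sample):
        by_deme[dm].append(lid)
    alive = n

    branch_masks: list[int] = []
    branch_lengths: list[float] = []
    t = 0.0
    events = 0
    rand = rng.random
    log = math.log
    isinf = math.isinf
    while alive > 1:
        events += 1
        if events > max_events:
            raise RuntimeError(
                f"coalescent event cap ({max_events}) exceeded; "
                "check migration/growth parameterization"
            )
        coal_w = [len(b) * (len(b) - 1) * 0.5 for b in by_deme]
        C = sum(coal_w)
        mig_w = [len(b) * r for b, r in zip(by_deme, out_rate_l)]
        R_mig = sum(mig_w)
        if C == 0.0 and R_mig == 0.0:
            raise RuntimeError(
                "no possible event: lineages isolated in separate demes with "
                "zero migration"
            )
        dt_c = _next_coal_increment(C, alpha, t, rng)
        dt_m = -log(1.0 - rand()) / R_mig if R_mig > 0 else math.inf
        if isinf(dt_c) and isinf(dt_m):
            raise RuntimeError("declining population: lineages cannot coalesce")
        if dt_c <= dt_m:
            t += dt_c
            if d > 1:
                r = rand() * C
                dm = 0
                acc = coal_w[0]
                while acc < r:
                    dm += 1
                    acc += coal_w[dm]
            else:
                dm = 0
            bucket = by_deme[dm]
            nb = len(bucket)
            i = int(rand() * nb)
            j = int(rand() * (nb - 1))
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            lid_j = bucket[j]
            lid_i = bucket[i]
            # record both children as branches
            for lid in (lid_i, lid_j):
                branch_masks.append(masks[lid])
                branch_lengths.append(t - births[lid])
            # merge into lid_i; remove lid_j by swap-pop
            masks[lid_i] = masks[lid_i] | masks[lid_j]
            births[lid_i] = t
            bucket[j] = bucket[-1]
            bucket.pop()
            alive -= 1
        else:
            t += dt_m
            # pick source deme weighted by lineage-count x out-rate
            r = rand() * R_mig
            dm = 0
            acc = mig_w[0]
            while acc < r:
                dm += 1
                acc += mig_w[dm]
            bucket = by_deme[dm]
            pos = int(rand() * len(bucket))
            lid = bucket[pos]
            bucket[pos] = bucket[-1]
            bucket.pop()
            cdf = dest_cdf[dm]
            dest = int(np.searchsorted(cdf, rand()))
            by_deme[dest].append(lid)

    return Genealogy(
        n=n,
        branch_masks=branch_masks,
        branch_lengths=np.asarray(branch_lengths),
        deme_of_sample=deme_of_sample,
        t_mrca=t,
    )


def _mask_to_column(mask: int, n: int) -> np.ndarray:
    col = np.zeros(n, dtype=np.uint8)
    m = mask
    while m:
        low = m & -m
        col[low.bit_length() - 1] = 1
        m ^= low
    return col


def drop_mutations(
    genealogy: Genealogy,
    S: Optional[int] = None,
    theta: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedLocus:
    """Place mutations uniformly on total branch length (infinite sites).

    Exactly one of ``S`` (conditioned number of segregating sites) or
    ``theta`` (scaled mutation rate; S ~ Poisson(theta * T_total / 2)) must
    be given.
    """
    rng = np.random.default_rng() if rng is None else rng
    if (S is None) == (theta is None):
        raise ValueError("give exactly one of S or theta")
    n = genealogy.n
    total = genealogy.total_branch_length
    if theta is not None:
        if theta <= 0:
            raise ValueError("theta must be positive")
        S = int(rng.poisson(theta * total / 2.0))
    if S < 0:
        raise ValueError("S must be non-negative")
    if S > 0 and n < 2:
        raise ValueError("cannot place mutations with n < 2")
    if S == 0:
        site_matrix = np.zeros((n, 0), dtype=np.uint8)
    else:
        cum = np.cumsum(genealogy.branch_lengths)
        pos = rng.uniform(0.0, total, size=S)
        idx = np.searchsorted(cum, pos, side="right")
        site_matrix = np.column_stack(
            [_mask_to_column(genealogy.branch_masks[i], n) for i in idx]
        )
    return SimulatedLocus(
        site_matrix=site_matrix,
        deme_of_sample=genealogy.deme_of_sample,
        total_branch_length=total,
        S=int(S),
    )


def sim_island_locus(
    sample_sizes: Sequence[int],
    d_demes: int,
    M: float,
    S: Optional[int] = None,
    theta: Optional[float] = None,
    alpha: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedLocus:
    """One locus under a strict finite island model with ``d_demes`` demes.

    ``sample_sizes`` gives gene copies for the first ``len(sample_sizes)``
    demes; the remaining demes are unsampled (they still shape the genealogy
    through migration).
    """
    if len(sample_sizes) > d_demes:
        raise ValueError("more sampled demes than demes")
    occupied = sum(1 for s in sample_sizes if s > 0)
    if d_demes > 1 and occupied > 1 and M <= 0:
        raise RuntimeError("M = 0 with samples in >= 2 demes can never coalesce")
    per_deme = list(sample_sizes) + [0] * (d_demes - len(sample_sizes))
    gen = sim_genealogy(per_deme, migration=M if d_demes > 1 else None,
                        alpha=alpha, rng=rng)
    return drop_mutations(gen, S=S, theta=theta, rng=rng)


def sim_tajima_d(n: int, S: int, rng: np.random.Generator) -> float:
    """Tajima's D of one neutral constant-size locus conditioned on S sites.

    Fast path used by the genome-wide null test: only derived-allele carrier
    counts are needed, not the full site matrix.
    """
    from .neutrality import tajima_constants

    if S <= 0:
        raise ValueError("S must be positive")
    gen = sim_genealogy(n, rng=rng)
    cum = np.cumsum(gen.branch_lengths)
    pos = rng.uniform(0.0, gen.total_branch_length, size=S)
    idx = np.searchsorted(cum, pos, side="right")
    c = np.array([gen.branch_masks[i].bit_count() for i in idx], dtype=float)
    k_hat = float((2.0 * c * (n - c)).sum() / (n * (n - 1)))
    const = tajima_constants(n)
    denom = np.sqrt(const.e1 * S + const.e2 * S * (S - 1))
    return (k_hat - S / const.a1) / denom
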