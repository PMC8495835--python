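"""Core domain model for multiallelic microhaplotype datasets.

A *microhaplotype locus* is a short sequenced fragment whose phased SNPs
define haplotype alleles; each allele is a DNA string over {A, C, G, T} and a
locus may carry many alleles (the motivating datasets range from 2 to 80
alleles per locus).  Genotypes are unordered diploid pairs of allele indices,
with explicit missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel allele index marking a missing gene copy.
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")

BASINS = ("atlantic", "gulf")
LIFE_STAGES = ("yoy", "juvenile", "adult")


class FormatError(ValueError):
    """Malformed input file or inconsistent in-memory structure."""


class ConsistencyError(ValueError):
    """Cross-referenced components of a dataset disagree."""


@dataclass(frozen=True)
class MicrohapLocus:
    """A microhaplotype locus: one contig with its catalogue of haplotype alleles."""

    locus_id: str
    contig: str
    length_bp: int
    alleles: tuple[str, ...]
    linkage_group: Optional[int] = None
    map_position_cM: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise FormatError(f"locus {self.locus_id}: needs at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise FormatError(f"locus {self.locus_id}: duplicate alleles")
        lens = {len(a) for a in self.alleles}
        if len(lens) != 1:
            raise FormatError(f"locus {self.locus_id}: allele strings differ in length")
        (allele_len,) = lens
        if allele_len > self.length_bp:
            raise FormatError(
                f"locus {self.locus_id}: allele length {allele_len} exceeds length_bp"
            )
        for a in self.alleles:
            if not set(a) <= _VALID_BASES:
                raise FormatError(f"locus {self.locus_id}: non-ACGT allele {a!r}")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class GenotypeMatrix:
    """Diploid allele-index calls for individuals x loci.

    ``calls`` has shape (n_loci, n_individuals, 2); entries are allele indices
    into the locus catalogue or :data:`MISSING`.  A genotype is either fully
    observed or fully missing (both gene copies).
    """

    individuals: list[str]
    loci: list[MicrohapLocus]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        expected = (len(self.loci), len(self.individuals), 2)
        if self.calls.shape != expected:
            raise FormatError(f"calls shape {self.calls.shape} != {expected}")
        for li, locus in enumerate(self.loci):
            row = self.calls[li]
            bad = (row >= locus.n_alleles) | ((row < 0) & (row != MISSING))
            if bad.any():
                raise FormatError(f"locus {locus.locus_id}: allele index out of range")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def locus_index(self) -> dict[str, int]:
        return {loc.locus_id: i for i, loc in enumerate(self.loci)}

    def observed_mask(self) -> np.ndarray:
        """(n_loci, n_individuals) bool: genotype fully observed."""
        return (self.calls != MISSING).all(axis=2)

    def gene_copy_counts(self) -> np.ndarray:
        """Per-locus number of observed gene copies n_l (recomputed, never cached)."""
        return 2 * self.observed_mask().sum(axis=1)

    def missing_fraction(self) -> np.ndarray:
        return 1.0 - self.observed_mask().mean(axis=1)

    def allele_counts(self, locus_i: int, individual_idx: Optional[np.ndarray] = None) -> np.ndarray:
        """Allele count vector at one locus over a subset of individuals."""
        row = self.calls[locus_i]
        if individual_idx is not None:
            row = row[individual_idx]
        obs = row[(row != MISSING).all(axis=1)]
        return np.bincount(obs.ravel(), minlength=self.loci[locus_i].n_alleles)

    def subset(self, individual_idx: Sequence[int] | np.ndarray | None = None,
               locus_idx: Sequence[int] | np.ndarray | None = None) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_individuals) if individual_idx is None else np.asarray(individual_idx)
        loc_idx = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in ind_idx],
            loci=[self.loci[i] for i in loc_idx],
            calls=self.calls[np.ix_(loc_idx, ind_idx)].copy(),
        )


@dataclass(frozen=True)
class SampleMetadata:
    """One genotyped individual with its estuary, basin, life stage, and coastline position."""

    individual_id: str
    estuary: str
    basin: str
    life_stage: str
    coastal_distance_km: float

    def __post_init__(self) -> None:
        if self.basin not in BASINS:
            raise FormatError(f"{self.individual_id}: unknown basin {self.basin!r}")
        if self.life_stage not in LIFE_STAGES:
            raise FormatError(f"{self.individual_id}: unknown life stage {self.life_stage!r}")
        if self.coastal_distance_km < 0:
            raise FormatError(f"{self.individual_id}: negative coastal distance")


@dataclass
class EnvTable:
    """Estuary-level environmental variables (mixed units; standardized downstream)."""

    table: pd.DataFrame  # index: estuary; columns: variables

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise FormatError("environmental table contains missing values")

    @property
    def estuaries(self) -> list[str]:
        return list(self.table.index)

    @property
    def variables(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class LinkageMap:
    """locus_id -> (linkage group 1..24, position in cM)."""

    table: pd.DataFrame  # columns: locus_id, linkage_group, position_cM

    def __post_init__(self) -> None:
        if self.table["locus_id"].duplicated().any():
            raise FormatError("linkage map: duplicated locus_id")
        lg = self.table["linkage_group"]
        if lg.nunique() > 24 or (lg < 1).any() or (lg > 24).any():
            raise FormatError("linkage map: linkage_group outside 1..24")
        if (self.table["position_cM"] < 0).any():
            raise FormatError("linkage map: negative position")

    def group_of(self) -> dict[str, int]:
        return dict(zip(self.table["locus_id"], self.table["linkage_group"].astype(int)))


@dataclass
class Dataset:
    """A genotype matrix cross-referenced with sample metadata and optional tables."""

    genotypes: GenotypeMatrix
    metadata: list[SampleMetadata]
    env: Optional[EnvTable] = None
    linkage_map: Optional[LinkageMap] = None
    _meta_by_id: dict[str, SampleMetadata] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.metadata]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("duplicated individual in metadata")
        geno_ids = set(self.genotypes.individuals)
        meta_ids = set(ids)
        if geno_ids != meta_ids:
            missing = sorted(geno_ids - meta_ids)[:5]
            extra = sorted(meta_ids - geno_ids)[:5]
            raise ConsistencyError(
                f"genotype/metadata individual mismatch (no metadata: {missing}; "
                f"not genotyped: {extra})"
            )
        # estuary -> basin must be a function
        basin_of: dict[str, str] = {}
        for m in self.metadata:
            if basin_of.setdefault(m.estuary, m.basin) != m.basin:
                raise ConsistencyError(f"estuary {m.estuary} mapped to two basins")
        self._meta_by_id = {m.individual_id: m for m in self.metadata}

    @property
    def individuals(self) -> list[str]:
        return self.genotypes.individuals

    def meta(self, individual_id: str) -> SampleMetadata:
        return self._meta_by_id[individual_id]

    def estuary_of(self) -> np.ndarray:
        """Estuary label per individual, aligned with genotype order."""
        return np.array([self._meta_by_id[i].estuary for i in self.individuals])

    def basin_of(self) -> np.ndarray:
        return np.array([self._meta_by_id[i].basin for i in self.individuals])

    def coastal_distance_of(self) -> np.ndarray:
        return np.array([self._meta_by_id[i].coastal_distance_km for i in self.individuals])

    def estuary_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for i in self.individuals:
            e = self._meta_by_id[i].estuary
            sizes[e] = sizes.get(e, 0) + 1
        return sizes

    def subset_individuals(self, keep: Sequence[str]) -> "Dataset":
        keep_set = set(keep)
        idx = [i for i, ind in enumerate(self.individuals) if ind in keep_set]
        geno = self.genotypes.subset(individual_idx=idx)
        meta = [m for m in self.metadata if m.individual_id in keep_set]
        return Dataset(geno, meta, env=self.env, linkage_map=self.linkage_map)


def filter_dataset(ds: Dataset, min_group_n: int = 18,
                   max_locus_missing: float = 1.0) -> Dataset:
    """Drop estuaries below a minimum sample size and loci above a missingness cap.

    The sample-size floor mirrors the common practice of requiring enough
    individuals per population sample for stable allele-frequency estimates;
    the landscape-genomics stage deliberately skips it (see
    :mod:`haplopop.rda`).  Returns a new Dataset; the input is untouched.
    Idempotent: filtering a filtered dataset is a no-op.
    """
    if min_group_n < 1:
        raise ValueError("min_group_n must be >= 1")
    sizes = ds.estuary_sizes()
    keep_estuaries = {e for e, n in sizes.items() if n >= min_group_n}
    if not keep_estuaries:
        raise ValueError("filter removed every estuary")
    keep_ids = [i for i in ds.individuals if ds.meta(i).estuary in keep_estuaries]
    out = ds.subset_individuals(keep_ids)
    miss = out.genotypes.missing_fraction()
    loc_idx = np.nonzero(miss <= max_locus_missing + 1e-12)[0]
    if len(loc_idx) == 0:
        raise ValueError("filter removed every locus")
    geno = out.genotypes.subset(locus_idx=loc_idx)
    return Dataset(geno, out.metadata, env=out.env, linkage_map=out.linkage_map)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in the input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
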