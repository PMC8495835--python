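"""Readers and writers for the package's external formats.

Formats
-------
Haplotype table (tab-separated, this package's dialect)
    Header: ``locus_id  contig  alleles  <ind1>  <ind2> ...``; one row per
    locus with a comma-separated allele catalogue and per-individual ``i/j``
    allele-index pairs (``./.`` = missing).
Metadata / environment / linkage-map tables
    Plain CSV with mandated column names (see the loader docstrings).
Genepop export
    One locus per line, 3-digit allele codes ranked by catalogue order, one
    ``Pop`` section per estuary — for interoperability with classic
    population-genetics software.
Phased VCF
    Standard VCF 4.x read through pysam; SNPs on one contig are collapsed
    into microhaplotype alleles.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    ConsistencyError,
    Dataset,
    EnvTable,
    FormatError,
    GenotypeMatrix,
    LinkageMap,
    MicrohapLocus,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

_HAP_FIXED_COLS = ("locus_id", "contig", "alleles")


# ---------------------------------------------------------------------------
# haplotype table

def read_haplotype_table(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:3]) != _HAP_FIXED_COLS:
            raise FormatError(f"{path}: header must start with {_HAP_FIXED_COLS}")
        individuals = header[3:]
        loci: list[MicrohapLocus] = []
        rows: list[np.ndarray] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + len(individuals):
                raise FormatError(f"{path}:{lineno}: expected {3+len(individuals)} fields")
            locus_id, contig, allele_field = fields[:3]
            if locus_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicated locus_id {locus_id}")
            seen.add(locus_id)
            alleles = tuple(allele_field.split(","))
            locus = MicrohapLocus(locus_id=locus_id, contig=contig,
                                  length_bp=len(alleles[0]), alleles=alleles)
            calls = np.empty((len(individuals), 2), dtype=np.int32)
            for k, cell in enumerate(fields[3:]):
                if cell == "./.":
                    calls[k] = MISSING
                else:
                    try:
                        a, b = cell.split("/")
                        calls[k] = (int(a), int(b))
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: bad call {cell!r}") from exc
            loci.append(locus)
            rows.append(calls)
    if not loci:
        raise FormatError(f"{path}: no loci")
    return GenotypeMatrix(individuals=list(individuals), loci=loci,
                          calls=np.stack(rows, axis=0))


def write_haplotype_table(geno: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_HAP_FIXED_COLS + tuple(geno.individuals)) + "\n")
        for li, locus in enumerate(geno.loci):
            cells = []
            for k in range(geno.n_individuals):
                a, b = geno.calls[li, k]
                cells.append("./." if a == MISSING else f"{a}/{b}")
            fh.write("\t".join([locus.locus_id, locus.contig,
                                ",".join(locus.alleles)] + cells) + "\n")


# ---------------------------------------------------------------------------
# CSV side tables

def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """CSV columns: individual_id, estuary, basin, life_stage, coastal_distance_km."""
    df = pd.read_csv(path)
    required = {"individual_id", "estuary", "basin", "life_stage", "coastal_distance_km"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(required)}")
    return [
        SampleMetadata(
            individual_id=str(r.individual_id), estuary=str(r.estuary),
            basin=str(r.basin), life_stage=str(r.life_stage),
            coastal_distance_km=float(r.coastal_distance_km),
        )
        for r in df.itertuples(index=False)
    ]


def write_metadata(metadata: list[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [(m.individual_id, m.estuary, m.basin, m.life_stage, m.coastal_distance_km)
         for m in metadata],
        columns=["individual_id", "estuary", "basin", "life_stage", "coastal_distance_km"],
    ).to_csv(path, index=False)


def read_env_table(path: str | Path) -> EnvTable:
    """CSV: column 'estuary' plus one column per environmental variable."""
    df = pd.read_csv(path)
    if "estuary" not in df.columns:
        raise FormatError(f"{path}: env table needs an 'estuary' column")
    df = df.set_index("estuary")
    return EnvTable(table=df.astype(float))


def write_env_table(env: EnvTable, path: str | Path) -> None:
    env.table.rename_axis("estuary").to_csv(path)


def read_linkage_map(path: str | Path) -> LinkageMap:
    """CSV columns: locus_id, linkage_group, position_cM."""
    df = pd.read_csv(path)
    required = {"locus_id", "linkage_group", "position_cM"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: linkage map needs columns {sorted(required)}")
    return LinkageMap(table=df[sorted(required)].copy())


def load_dataset(genotype_path: str | Path, metadata_path: str | Path,
                 env_path: Optional[str | Path] = None,
                 map_path: Optional[str | Path] = None) -> Dataset:
    """Load and cross-reference all dataset components.

    Individuals present in one file but not the other are an error, never
    silently dropped.
    """
    geno = read_haplotype_table(genotype_path)
    meta = read_metadata(metadata_path)
    env = read_env_table(env_path) if env_path is not None else None
    lmap = read_linkage_map(map_path) if map_path is not None else None
    return Dataset(genotypes=geno, metadata=meta, env=env, linkage_map=lmap)


# ---------------------------------------------------------------------------
# genepop export

def write_genepop(geno: GenotypeMatrix, populations: dict[str, str] | pd.Series,
                  path: str | Path, title: str = "haplopop export") -> None:
    """Genepop format with 3-digit allele codes (catalogue order, 1-based)."""
    for locus in geno.loci:
        if locus.n_alleles > 999:
            raise FormatError(f"{locus.locus_id}: >999 alleles, not genepop-encodable")
    pops = pd.Series(dict(populations)) if not isinstance(populations, pd.Series) else populations
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in geno.loci:
            fh.write(locus.locus_id + "\n")
        for pop in pd.unique(pops.loc[geno.individuals]):
            fh.write("Pop\n")
            for k, ind in enumerate(geno.individuals):
                if pops[ind] != pop:
                    continue
                codes = []
                for li in range(geno.n_loci):
                    a, b = geno.calls[li, k]
                    codes.append("000000" if a == MISSING else f"{a+1:03d}{b+1:03d}")
                fh.write(f"{ind}, " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# phased VCF collapsing

def collapse_phased_vcf(vcf_path: str | Path) -> tuple[list[MicrohapLocus], GenotypeMatrix]:
    """Collapse phased SNPs per contig into microhaplotype alleles.

    Each contig becomes one locus; each phased haplotype across the contig's
    variant sites (concatenated in coordinate order) becomes one allele
    string.  Individuals with any unphased or missing site at a contig are
    MISSING at that locus (counted and logged, not fatal).  Contigs with no
    variant sites are skipped.
    """
    import pysam

    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    by_contig: dict[str, list] = {}
    for rec in vcf:
        by_contig.setdefault(rec.chrom, []).append(rec)
    vcf.close()

    loci: list[MicrohapLocus] = []
    rows: list[np.ndarray] = []
    n_unphased = 0
    for contig in by_contig:
        recs = sorted(by_contig[contig], key=lambda r: r.pos)
        hap_a: list[list[str]] = [[] for _ in samples]
        hap_b: list[list[str]] = [[] for _ in samples]
        ok = np.ones(len(samples), dtype=bool)
        for rec in recs:
            alleles_site = (rec.ref,) + tuple(rec.alts or ())
            for si, sample in enumerate(samples):
                call = rec.samples[si]
                gt = call["GT"]
                if gt is None or len(gt) != 2 or None in gt:
                    ok[si] = False
                    continue
                if not call.phased:
                    ok[si] = False
                    n_unphased += 1
                    continue
                hap_a[si].append(alleles_site[gt[0]])
                hap_b[si].append(alleles_site[gt[1]])
        strings: list[tuple[str, str] | None] = []
        for si in range(len(samples)):
            if ok[si]:
                strings.append(("".join(hap_a[si]), "".join(hap_b[si])))
            else:
                strings.append(None)
        catalogue: list[str] = []
        index: dict[str, int] = {}
        calls = np.full((len(samples), 2), MISSING, dtype=np.int32)
        for si, pair in enumerate(strings):
            if pair is None:
                continue
            for j, s in enumerate(pair):
                if s not in index:
                    index[s] = len(catalogue)
                    catalogue.append(s)
                calls[si, j] = index[s]
        if not catalogue:
            continue
        locus = MicrohapLocus(locus_id=contig, contig=contig,
                              length_bp=len(catalogue[0]), alleles=tuple(catalogue))
        loci.append(locus)
        rows.append(calls)
    if n_unphased:
        logger.warning("collapse_phased_vcf: %d unphased genotypes set to missing", n_unphased)
    if not loci:
        raise FormatError(f"{vcf_path}: no polymorphic contigs")
    geno = GenotypeMatrix(individuals=samples, loci=loci, calls=np.stack(rows, axis=0))
    return loci, geno
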