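"""Domain model, file dialects, filtering, and the BH step-up correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haplopop import (
    ConsistencyError,
    Dataset,
    FormatError,
    GenotypeMatrix,
    MicrohapLocus,
    SampleMetadata,
    bh_adjust,
    collapse_phased_vcf,
    filter_dataset,
    load_dataset,
    write_genepop,
    write_haplotype_table,
)
from haplopop.io import read_haplotype_table, write_metadata
from haplopop.simulate import write_scenario

# Published per-estuary sample sizes used as the canonical filtering example.
FIG1_SIZES = {
    "SA": 23, "MAT": 3, "GB": 2, "SL": 24, "BB": 39, "WMS": 34, "EMS": 5,
    "MB": 62, "AP": 44, "SJR": 20, "SHS": 4, "Stono": 4, "CH": 18, "SR": 4,
    "WB": 18,
}


class TestModel:
    def test_gene_copy_bookkeeping(self, toy_geno):
        assert toy_geno.gene_copy_counts().tolist() == [6, 6]
        toy_geno.calls[0, 1] = -1  # one missing genotype at locus 1
        assert toy_geno.gene_copy_counts().tolist() == [4, 6]

    def test_locus_invariants(self):
        with pytest.raises(FormatError):
            MicrohapLocus("L", "c", 2, ("AA", "AA"))
        with pytest.raises(FormatError):
            MicrohapLocus("L", "c", 2, ("AA", "ANT"))
        with pytest.raises(FormatError):
            MicrohapLocus("L", "c", 1, ("AA",))

    def test_metadata_mismatch_is_error(self, toy_geno):
        meta = [SampleMetadata("i1", "e", "gulf", "yoy", 0.0),
                SampleMetadata("i2", "e", "gulf", "yoy", 0.0)]
        with pytest.raises(ConsistencyError):
            Dataset(genotypes=toy_geno, metadata=meta)

    def test_estuary_basin_must_be_function(self, toy_geno):
        meta = [SampleMetadata("i1", "e", "gulf", "yoy", 0.0),
                SampleMetadata("i2", "e", "atlantic", "yoy", 0.0),
                SampleMetadata("i3", "e", "gulf", "yoy", 0.0)]
        with pytest.raises(ConsistencyError):
            Dataset(genotypes=toy_geno, metadata=meta)


class TestHaplotypeTable:
    def test_round_trip_identity(self, tmp_path, gulf_scenario):
        ds, _ = gulf_scenario
        path = tmp_path / "haps.tsv"
        write_haplotype_table(ds.genotypes, path)
        back = read_haplotype_table(path)
        assert back.individuals == ds.genotypes.individuals
        assert np.array_equal(back.calls, ds.genotypes.calls)
        assert [l.alleles for l in back.loci] == [l.alleles for l in ds.genotypes.loci]

    def test_duplicate_locus_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("locus_id\tcontig\talleles\ti1\n"
                        "L1\tc1\tA,T\t0/1\nL1\tc1\tA,T\t0/0\n")
        with pytest.raises(FormatError, match="duplicated locus_id"):
            read_haplotype_table(path)

    def test_non_acgt_allele_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("locus_id\tcontig\talleles\ti1\nL1\tc1\tA,N\t0/1\n")
        with pytest.raises(FormatError):
            read_haplotype_table(path)

    def test_load_dataset_cross_references(self, tmp_path, toy_geno):
        write_haplotype_table(toy_geno, tmp_path / "h.tsv")
        meta = [SampleMetadata(i, "e", "gulf", "yoy", 0.0)
                for i in ("i1", "i2", "i3")]
        write_metadata(meta, tmp_path / "m.csv")
        ds = load_dataset(tmp_path / "h.tsv", tmp_path / "m.csv")
        assert ds.genotypes.gene_copy_counts().tolist() == [6, 6]
        # an unknown individual in metadata is an error, not dropped
        write_metadata(meta + [SampleMetadata("ghost", "e", "gulf", "yoy", 0.0)],
                       tmp_path / "m2.csv")
        with pytest.raises(ConsistencyError):
            load_dataset(tmp_path / "h.tsv", tmp_path / "m2.csv")

    def test_scenario_files_reload(self, tmp_path, gulf_scenario):
        ds, _ = gulf_scenario
        write_scenario(ds, gulf_scenario[1], tmp_path)
        back = load_dataset(tmp_path / "haplotypes.tsv", tmp_path / "metadata.csv",
                            env_path=tmp_path / "environment.csv",
                            map_path=tmp_path / "linkage_map.csv")
        assert np.array_equal(back.genotypes.calls, ds.genotypes.calls)
        assert back.env.table.shape == ds.env.table.shape


class TestFilter:
    def _dataset_with_sizes(self, sizes: dict[str, int]) -> Dataset:
        inds, meta = [], []
        k = 0
        for est, n in sizes.items():
            basin = "gulf" if est in ("SA", "MAT", "GB", "SL", "BB", "WMS",
                                      "EMS", "MB", "AP") else "atlantic"
            for _ in range(n):
                iid = f"{est}_{k}"
                inds.append(iid)
                meta.append(SampleMetadata(iid, est, basin, "yoy", 0.0))
                k += 1
        loci = [MicrohapLocus("L1", "c1", 1, ("A", "T"))]
        calls = np.zeros((1, len(inds), 2), dtype=np.int32)
        return Dataset(GenotypeMatrix(inds, loci, calls), meta)

    def test_published_sizes_leave_nine_estuaries(self):
        ds = filter_dataset(self._dataset_with_sizes(FIG1_SIZES), min_group_n=18)
        assert len(ds.estuary_sizes()) == 9
        assert set(ds.estuary_sizes()) == {"SA", "SL", "BB", "WMS", "MB", "AP",
                                           "SJR", "CH", "WB"}

    def test_min_one_is_identity_and_idempotent(self):
        ds = self._dataset_with_sizes(FIG1_SIZES)
        same = filter_dataset(ds, min_group_n=1)
        assert same.estuary_sizes() == ds.estuary_sizes()
        once = filter_dataset(ds, min_group_n=18)
        twice = filter_dataset(once, min_group_n=18)
        assert once.individuals == twice.individuals

    def test_zero_missing_tolerance_drops_locus(self, toy_dataset):
        toy_dataset.genotypes.calls[0, 0] = -1
        out = filter_dataset(toy_dataset, min_group_n=1, max_locus_missing=0.0)
        assert out.genotypes.n_loci == 1
        assert out.genotypes.loci[0].locus_id == "L2"

    def test_everything_removed_is_error(self, toy_dataset):
        with pytest.raises(ValueError):
            filter_dataset(toy_dataset, min_group_n=100)


class TestBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
    ])
    def test_step_up_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=50))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()


class TestGenepop:
    def test_export_structure(self, tmp_path, toy_geno):
        path = tmp_path / "out.gen"
        write_genepop(toy_geno, {"i1": "A", "i2": "A", "i3": "B"}, path)
        lines = path.read_text().splitlines()
        assert lines[1:3] == ["L1", "L2"]
        assert lines.count("Pop") == 2
        # catalogue-ranked 3-digit codes, 1-based
        assert "i1, 001002 001001" in lines


class TestVcfCollapse:
    VCF = """##fileformat=VCFv4.2
##contig=<ID=ctg1>
##contig=<ID=ctg2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
ctg1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
ctg1\t20\t.\tG\tT\t.\tPASS\t.\tGT\t1|1\t1|1\t0/1
ctg2\t5\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|0\t0|0
"""

    def test_collapse(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(self.VCF)
        loci, geno = collapse_phased_vcf(vcf)
        by_id = {l.locus_id: l for l in loci}
        # s1 at ctg1: haplotypes A|G at pos10 + T|T at pos20 -> "AT","GT"
        ctg1 = by_id["ctg1"]
        i = geno.locus_index()["ctg1"]
        s1 = [ctg1.alleles[a] for a in geno.calls[i, 0]]
        assert sorted(s1) == ["AT", "GT"]
        # s3 has an unphased site at ctg1 -> missing there
        assert (geno.calls[i, 2] == -1).all()
        # monomorphic contig: single-allele locus
        assert by_id["ctg2"].alleles == ("C",)
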