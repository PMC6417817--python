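"""Allele-library parsing and unique-k-mer extraction."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kircall import (
    AlleleLibrary,
    extract_unique_kmers,
    load_allele_library,
    load_index,
    select_background_kmers,
    write_index,
)
from kircall._kmers import canonical, reverse_complement
from kircall.exceptions import (
    ConfigError,
    FastaError,
    KircallWarning,
    ParameterError,
)

from oracles import brute_force_unique_kmers, random_toy_library


class TestLoadAlleleLibrary:
    def test_groups_records_by_gene(self):
        fasta = io.StringIO(">GENEA*001\nACGTACGT\n>GENEA*002\nACGTACGA\n")
        lib = load_allele_library(fasta)
        assert lib.gene_names == ["GENEA"]
        assert lib.genes["GENEA"] == [("001", "ACGTACGT"), ("002", "ACGTACGA")]

    def test_sequences_uppercased_and_order_preserved(self):
        fasta = io.StringIO(">G*2\nacgt\n>G*1\nTTTT\n")
        lib = load_allele_library(fasta)
        assert lib.genes["G"] == [("2", "ACGT"), ("1", "TTTT")]

    def test_empty_fasta_rejected(self):
        with pytest.raises(FastaError, match="no records"):
            load_allele_library(io.StringIO(""))

    def test_nonconforming_header_named_in_error(self):
        with pytest.raises(FastaError, match="weird-header"):
            load_allele_library(io.StringIO(">weird-header\nACGT\n"))

    def test_duplicate_gene_allele_pair_rejected(self):
        fasta = io.StringIO(">G*1\nACGT\n>G*1\nACGT\n")
        with pytest.raises(FastaError, match="duplicate"):
            load_allele_library(fasta)

    def test_simulated_library_roundtrips_through_fasta(self, tmp_path):
        from kircall import SimulationConfig, simulate_allele_library

        cfg = SimulationConfig(seed=3, n_samples=50, allele_length=200)
        lib = simulate_allele_library(cfg)
        path = tmp_path / "lib.fasta"
        lib.write_fasta(path)
        reloaded = load_allele_library(path)
        assert reloaded.genes == lib.genes


class TestExtractUniqueKmers:
    def test_identical_genes_have_no_unique_kmers(self):
        lib = AlleleLibrary(
            {"A": [("1", "ACGTACGTAC")], "B": [("1", "ACGTACGTAC")]}
        )
        with pytest.warns(KircallWarning):
            idx = extract_unique_kmers(lib, 4)
        assert idx.per_gene["A"] == frozenset()
        assert idx.per_gene["B"] == frozenset()

    def test_matches_bruteforce_on_worked_example(self, tiny_library):
        idx = extract_unique_kmers(tiny_library, 4)
        oracle = brute_force_unique_kmers(
            {g: [s for _, s in a] for g, a in tiny_library.genes.items()}, 4
        )
        assert {g: set(s) for g, s in idx.per_gene.items()} == oracle

    @pytest.mark.parametrize("k", [4, 10, 15, 30])
    def test_matches_bruteforce_on_random_library(self, k):
        rng = np.random.default_rng(k)
        genes = random_toy_library(rng)
        lib = AlleleLibrary(
            {g: [(f"{i:03d}", s) for i, s in enumerate(a)] for g, a in genes.items()}
        )
        idx = extract_unique_kmers(lib, k)
        assert {g: set(s) for g, s in idx.per_gene.items()} == brute_force_unique_kmers(genes, k)

    def test_ambiguous_bases_never_yield_candidates(self):
        lib = AlleleLibrary(
            {"A": [("1", "AANCCTTGG")], "B": [("1", "TTACGCGCG")]}
        )
        idx = extract_unique_kmers(lib, 4)
        assert all("N" not in km for km in idx.per_gene["A"])
        # windows covering the N are absent even though unique otherwise
        assert canonical("AANC") not in idx.per_gene["A"]

    def test_k_below_one_rejected(self, tiny_library):
        with pytest.raises(ParameterError):
            extract_unique_kmers(tiny_library, 0)

    def test_k_longer_than_all_alleles_warns_and_returns_empty(self, tiny_library):
        with pytest.warns(KircallWarning):
            idx = extract_unique_kmers(tiny_library, 99)
        assert all(not s for s in idx.per_gene.values())

    def test_min_allele_length_excludes_partial_records(self):
        lib = AlleleLibrary(
            {"A": [("full", "ACGTACGTACGT"), ("partial", "ACGT")], "B": [("1", "TTTTCCCCGGGA")]}
        )
        strict = extract_unique_kmers(lib, 8)
        relaxed = extract_unique_kmers(lib, 8, min_allele_length=8)
        assert not strict.per_gene["A"]  # partial allele vetoes everything
        assert relaxed.per_gene["A"]

    @pytest.mark.parametrize("k", [4, 15, 30])
    def test_index_sets_pairwise_disjoint_and_canonical(self, k):
        rng = np.random.default_rng(100 + k)
        genes = random_toy_library(rng)
        lib = AlleleLibrary(
            {g: [(f"{i:03d}", s) for i, s in enumerate(a)] for g, a in genes.items()}
        )
        idx = extract_unique_kmers(lib, k)
        seen = set()
        for kmers in idx.per_gene.values():
            assert not (kmers & seen)
            seen |= kmers
            for km in kmers:
                assert canonical(km) == km
                assert canonical(reverse_complement(km)) == km


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=40))
def test_canonical_closure(kmer):
    """canonical() is idempotent and strand-invariant."""
    c = canonical(kmer)
    assert canonical(c) == c
    assert canonical(reverse_complement(kmer)) == c
    assert c <= reverse_complement(c)


class TestBackgroundSelection:
    @pytest.fixture()
    def kir_and_background(self, rng):
        kir = AlleleLibrary(
            {"KIR1": [("1", "".join(rng.choice(list("ACGT"), size=300)))]}
        )
        bg = AlleleLibrary(
            {
                f"BG{i}": [("1", "".join(rng.choice(list("ACGT"), size=1000)))]
                for i in range(5)
            }
        )
        return kir, bg

    def test_caps_at_max_per_gene_and_respects_eligibility(self, kir_and_background):
        kir, bg = kir_and_background
        idx = extract_unique_kmers(kir, 30)
        sel = select_background_kmers(
            bg, idx, kir_library=kir, k=30, max_per_gene=10, seed=1
        )
        genes = {g: [s for _, s in a] for g, a in bg.genes.items()}
        genes["KIR1"] = [s for _, s in kir.genes["KIR1"]]
        eligible = brute_force_unique_kmers(genes, 30)
        for gene, chosen in sel.per_gene.items():
            assert len(chosen) == 10
            assert chosen <= eligible[gene]
            assert not (chosen & idx.per_gene["KIR1"])

    def test_same_seed_reproduces_selection_exactly(self, kir_and_background):
        kir, bg = kir_and_background
        idx = extract_unique_kmers(kir, 30)
        a = select_background_kmers(bg, idx, kir_library=kir, seed=7)
        b = select_background_kmers(bg, idx, kir_library=kir, seed=7)
        assert a.per_gene == b.per_gene

    def test_background_gene_copying_a_kir_allele_is_empty(self, kir_and_background):
        kir, _ = kir_and_background
        clone = AlleleLibrary({"BGCLONE": [("1", kir.genes["KIR1"][0][1])]})
        idx = extract_unique_kmers(kir, 30)
        with pytest.warns(KircallWarning, match="BGCLONE"):
            sel = select_background_kmers(clone, idx, kir_library=kir)
        assert sel.per_gene["BGCLONE"] == frozenset()

    def test_k_mismatch_with_index_rejected(self, kir_and_background):
        kir, bg = kir_and_background
        idx = extract_unique_kmers(kir, 30)
        with pytest.raises(ParameterError):
            select_background_kmers(bg, idx, kir_library=kir, k=25)

    def test_gene_overlap_with_kir_rejected(self, kir_and_background):
        kir, _ = kir_and_background
        idx = extract_unique_kmers(kir, 30)
        with pytest.raises(ConfigError):
            select_background_kmers(kir, idx, k=30)


def test_index_tsv_json_roundtrip(tmp_path, tiny_library):
    idx = extract_unique_kmers(tiny_library, 4)
    write_index(idx, tmp_path / "idx")
    reloaded = load_index(tmp_path / "idx")
    assert reloaded.k == idx.k
    assert reloaded.per_gene == idx.per_gene
    assert reloaded.provenance == idx.provenance
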