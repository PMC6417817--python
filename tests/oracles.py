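"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation strategy: presence
is tested by Python substring search on raw sequences, canonicalization
by direct string comparison, and counting by an explicit per-read
sliding-window scan.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[ch] for ch in reversed(seq))


def canon(kmer: str) -> str:
    r = rc(kmer)
    return kmer if kmer <= r else r


def all_windows(seq: str, k: int) -> list[str]:
    return [
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if all(ch in "ACGT" for ch in seq[i : i + k])
    ]


def present(kmer: str, seq: str) -> bool:
    """Does the k-mer occur in the sequence, directly or as its RC?"""
    return kmer in seq or rc(kmer) in seq


def brute_force_unique_kmers(
    genes: dict[str, list[str]], k: int
) -> dict[str, set[str]]:
    """Enumerate every k-mer of every allele; keep those present in all
    alleles of one gene and in no allele of any other gene."""
    out: dict[str, set[str]] = {}
    for gene, alleles in genes.items():
        candidates = {canon(w) for seq in alleles for w in all_windows(seq, k)}
        unique = set()
        for km in candidates:
            if not all(present(km, seq) for seq in alleles):
                continue
            if any(
                present(km, seq)
                for other, other_alleles in genes.items()
                if other != gene
                for seq in other_alleles
            ):
                continue
            unique.add(km)
        out[gene] = unique
    return out


def naive_count(
    reads: list[str], kmer_to_gene: dict[str, str], k: int
) -> tuple[dict[str, int], dict[str, int]]:
    """Sliding-window occurrence counts and per-gene reads-with-hit."""
    counts: dict[str, int] = {}
    reads_with_hit: dict[str, int] = {}
    for read in reads:
        genes_hit: set[str] = set()
        for i in range(len(read) - k + 1):
            window = read[i : i + k]
            if any(ch not in "ACGT" for ch in window):
                continue
            cw = canon(window)
            if cw in kmer_to_gene:
                counts[cw] = counts.get(cw, 0) + 1
                genes_hit.add(kmer_to_gene[cw])
        for g in genes_hit:
            reads_with_hit[g] = reads_with_hit.get(g, 0) + 1
    return counts, reads_with_hit


def random_toy_library(rng, max_genes=10, max_alleles=5, max_len=500) -> dict[str, list[str]]:
    """Random homologous toy library: genes share segments so that many
    k-mers are non-unique."""
    n_genes = int(rng.integers(2, max_genes + 1))
    shared_len = int(rng.integers(0, max_len // 2))
    shared = "".join(rng.choice(list("ACGT"), size=shared_len))
    genes: dict[str, list[str]] = {}
    for gi in range(n_genes):
        base_len = int(rng.integers(20, max_len - shared_len + 1))
        own = "".join(rng.choice(list("ACGT"), size=base_len))
        base = shared + own if rng.random() < 0.5 else own + shared
        n_alleles = int(rng.integers(1, max_alleles + 1))
        alleles = [base]
        for _ in range(n_alleles - 1):
            seq = list(base)
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(0, len(seq)))
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            alleles.append("".join(seq))
        genes[f"G{gi:02d}"] = alleles
    return genes
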