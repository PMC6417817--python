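"""Multi-allele gene references and unique k-mer indexes.

The KIR locus is a cluster of up to 16 highly homologous genes; short reads
cannot be assigned to a gene by alignment alone.  The disambiguation
primitive used throughout this package is the *unique k-mer*: a length-k
substring that (as itself or as its reverse complement) occurs in **every
allele of exactly one gene** and in **no allele of any other gene** in the
reference.  Coverage of a gene's unique k-mers is then proportional to the
gene's copy number, regardless of where the reads would map.

Alongside the gene index, a panel of *background genes* drawn from
elsewhere in the genome contributes k-mers whose coverage tracks overall
sequencing depth; these anchor the depth normalization.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
from Bio import SeqIO

from ._kmers import canonical_windows
from .exceptions import ConfigError, FastaError, KircallWarning, ParameterError

#: Default header convention: ``GENE*allele`` as used by IPD-KIR releases.
DEFAULT_HEADER_REGEX = r"^(?P<gene>[^*\s]+)\*(?P<allele>\S+)"


@dataclass
class AlleleLibrary:
    """Gene -> ordered list of (allele id, nucleotide sequence).

    Invariants: every gene has at least one allele, sequences are
    non-empty upper-case strings over {A,C,G,T,N}, allele ids are unique
    within a gene and gene ids within the library.
    """

    genes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    name: str = "library"

    def __post_init__(self) -> None:
        for gene, alleles in self.genes.items():
            if not alleles:
                raise FastaError(f"gene {gene!r} has no alleles")
            seen = set()
            for allele, seq in alleles:
                if not seq:
                    raise FastaError(f"empty sequence for {gene}*{allele}")
                if allele in seen:
                    raise FastaError(f"duplicate allele {gene}*{allele}")
                seen.add(allele)

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes)

    @property
    def n_alleles(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def checksum(self) -> str:
        """MD5 over the (gene, allele, sequence) triples, order-independent."""
        h = hashlib.md5()
        for gene in sorted(self.genes):
            for allele, seq in sorted(self.genes[gene]):
                h.update(f"{gene}\t{allele}\t{seq}\n".encode())
        return h.hexdigest()

    def subset(self, genes: Iterable[str]) -> "AlleleLibrary":
        return AlleleLibrary(
            {g: list(self.genes[g]) for g in genes}, name=self.name
        )

    def filter_min_length(self, min_allele_length: int) -> "AlleleLibrary":
        """Drop allele records shorter than ``min_allele_length``.

        Partial reference entries shorter than any real transcript would
        otherwise veto every k-mer of their gene under the every-allele
        criterion.
        """
        kept = {}
        for gene, alleles in self.genes.items():
            sub = [(a, s) for a, s in alleles if len(s) >= min_allele_length]
            if sub:
                kept[gene] = sub
        return AlleleLibrary(kept, name=self.name)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene, alleles in self.genes.items():
                for allele, seq in alleles:
                    fh.write(f">{gene}*{allele}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")


def load_allele_library(
    fasta_source: str | Path | IO[str],
    header_regex: str = DEFAULT_HEADER_REGEX,
    name: str | None = None,
) -> AlleleLibrary:
    """Load a multi-allele FASTA into an :class:`AlleleLibrary`.

    ``header_regex`` must expose named groups ``gene`` and ``allele``; the
    default matches IPD-style ``GENE*allele`` identifiers.  Record order is
    preserved within each gene and sequences are upper-cased.
    """
    pattern = re.compile(header_regex)
    if "gene" not in pattern.groupindex or "allele" not in pattern.groupindex:
        raise ParameterError("header_regex needs named groups 'gene' and 'allele'")

    close = False
    if isinstance(fasta_source, (str, Path)):
        path = Path(fasta_source)
        handle = (
            gzip.open(path, "rt") if path.suffix == ".gz" else open(path)
        )
        close = True
        if name is None:
            name = path.name
    else:
        handle = fasta_source
        name = name or "stream"

    genes: dict[str, list[tuple[str, str]]] = {}
    try:
        for record in SeqIO.parse(handle, "fasta"):
            header = record.description or record.id
            m = pattern.match(header)
            if m is None:
                raise FastaError(
                    f"header {header!r} does not match the naming convention"
                )
            gene, allele = m.group("gene"), m.group("allele")
            seq = str(record.seq).upper()
            if not seq:
                raise FastaError(f"record {header!r} has an empty sequence")
            if any(a == allele for a, _ in genes.get(gene, [])):
                raise FastaError(f"duplicate record for {gene}*{allele}")
            genes.setdefault(gene, []).append((allele, seq))
    finally:
        if close:
            handle.close()
    if not genes:
        raise FastaError("no records in FASTA input")
    return AlleleLibrary(genes, name=name)


@dataclass
class UniqueKmerIndex:
    """Per-gene sets of canonical unique k-mers.

    The per-gene sets are pairwise disjoint by construction; a gene with no
    k-mer satisfying the every-allele/no-other-gene criterion maps to an
    empty set and is handled downstream by co-segregation inference.
    """

    k: int
    per_gene: dict[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for gene, kmers in self.per_gene.items():
            for km in kmers:
                if km in seen:
                    raise ConfigError(
                        f"k-mer {km} shared between {seen[km]} and {gene}"
                    )
                seen[km] = gene

    @property
    def genes_with_kmers(self) -> list[str]:
        return [g for g, s in self.per_gene.items() if s]

    @property
    def all_kmers(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.per_gene.values():
            out |= s
        return frozenset(out)

    def n_kmers(self, gene: str) -> int:
        return len(self.per_gene[gene])


@dataclass
class BackgroundKmerSet:
    """Canonical k-mers for the depth-normalization gene panel."""

    k: int
    per_gene: dict[str, frozenset[str]]
    max_per_gene: int = 100
    provenance: str = ""

    def __post_init__(self) -> None:
        for gene, kmers in self.per_gene.items():
            if len(kmers) > self.max_per_gene:
                raise ConfigError(
                    f"background gene {gene} has {len(kmers)} k-mers "
                    f"(max_per_gene={self.max_per_gene})"
                )

    @property
    def all_kmers(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.per_gene.values():
            out |= s
        return frozenset(out)


def extract_unique_kmers(
    library: AlleleLibrary, k: int, min_allele_length: int = 0
) -> UniqueKmerIndex:
    """Compute the unique-k-mer index of a library.

    A canonical k-mer belongs to gene ``g`` iff it occurs (directly or via
    reverse complement) in every allele of ``g`` and in no allele of any
    other gene.  k-mers containing a non-ACGT base are never candidates.
    ``min_allele_length`` optionally drops short/partial allele records
    before applying the every-allele criterion.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    lib = library.filter_min_length(min_allele_length) if min_allele_length else library

    core: dict[str, set[str]] = {}
    occurs: dict[str, set[str]] = {}
    for gene, alleles in lib.genes.items():
        allele_sets = [canonical_windows(seq, k) for _, seq in alleles]
        core[gene] = set.intersection(*allele_sets) if allele_sets else set()
        occurs[gene] = set.union(*allele_sets) if allele_sets else set()

    n_genes_with: dict[str, int] = {}
    for gene, kmers in occurs.items():
        for km in kmers:
            n_genes_with[km] = n_genes_with.get(km, 0) + 1

    per_gene = {
        gene: frozenset(km for km in kmers if n_genes_with[km] == 1)
        for gene, kmers in core.items()
    }
    if not any(per_gene.values()):
        warnings.warn(
            f"no unique k-mers at k={k} for any gene",
            KircallWarning,
            stacklevel=2,
        )
    return UniqueKmerIndex(k=k, per_gene=per_gene, provenance=lib.checksum())


def select_background_kmers(
    background_library: AlleleLibrary,
    kir_index: UniqueKmerIndex,
    *,
    kir_library: AlleleLibrary | None = None,
    k: int = 30,
    max_per_gene: int = 100,
    seed: int = 0,
) -> BackgroundKmerSet:
    """Pick up to ``max_per_gene`` k-mers per background gene.

    Eligibility requires presence in every allele of the background gene
    and absence from every other background gene *and* from every KIR
    allele (given ``kir_library``; otherwise from the indexed KIR k-mers),
    so that background coverage can never absorb KIR signal.  Selection
    among eligible k-mers is a seeded shuffle of the sorted eligible set.
    """
    if k != kir_index.k:
        raise ParameterError(
            f"background k={k} does not match KIR index k={kir_index.k}"
        )
    overlap = set(background_library.genes) & set(kir_index.per_gene)
    if overlap:
        raise ConfigError(f"background genes overlap KIR genes: {sorted(overlap)}")

    core: dict[str, set[str]] = {}
    occurs: dict[str, set[str]] = {}
    for gene, alleles in background_library.genes.items():
        allele_sets = [canonical_windows(seq, k) for _, seq in alleles]
        core[gene] = set.intersection(*allele_sets)
        occurs[gene] = set.union(*allele_sets)

    kir_kmers: set[str] = set(kir_index.all_kmers)
    if kir_library is not None:
        for alleles in kir_library.genes.values():
            for _, seq in alleles:
                kir_kmers |= canonical_windows(seq, k)

    rng = np.random.default_rng(seed)
    per_gene: dict[str, frozenset[str]] = {}
    for gene in background_library.genes:
        eligible = set(core[gene]) - kir_kmers
        for other, kmers in occurs.items():
            if other != gene:
                eligible -= kmers
        ordered = sorted(eligible)
        rng.shuffle(ordered)
        chosen = ordered[:max_per_gene]
        if not chosen:
            warnings.warn(
                f"background gene {gene} has no eligible k-mers",
                KircallWarning,
                stacklevel=2,
            )
        per_gene[gene] = frozenset(chosen)
    return BackgroundKmerSet(
        k=k,
        per_gene=per_gene,
        max_per_gene=max_per_gene,
        provenance=background_library.checksum(),
    )


# ---------------------------------------------------------------------------
# Serialization: TSV of (gene, kmer) plus a JSON sidecar with parameters.
# ---------------------------------------------------------------------------


def write_index(index: UniqueKmerIndex | BackgroundKmerSet, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        fh.write("gene\tkmer\n")
        for gene in sorted(index.per_gene):
            for km in sorted(index.per_gene[gene]):
                fh.write(f"{gene}\t{km}\n")
    meta: dict = {
        "k": index.k,
        "provenance": index.provenance,
        "genes": sorted(index.per_gene),
        "kind": "background" if isinstance(index, BackgroundKmerSet) else "unique",
    }
    if isinstance(index, BackgroundKmerSet):
        meta["max_per_gene"] = index.max_per_gene
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_index(prefix: str | Path) -> UniqueKmerIndex | BackgroundKmerSet:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    per_gene: dict[str, set[str]] = {g: set() for g in meta["genes"]}
    with open(prefix.with_suffix(".tsv")) as fh:
        header = fh.readline()
        if header.strip() != "gene\tkmer":
            raise FastaError(f"unexpected index header {header!r}")
        for line in fh:
            gene, km = line.rstrip("\n").split("\t")
            per_gene.setdefault(gene, set()).add(km)
    frozen = {g: frozenset(s) for g, s in per_gene.items()}
    if meta.get("kind") == "background":
        return BackgroundKmerSet(
            k=meta["k"],
            per_gene=frozen,
            max_per_gene=meta.get("max_per_gene", 100),
            provenance=meta.get("provenance", ""),
        )
    return UniqueKmerIndex(
        k=meta["k"], per_gene=frozen, provenance=meta.get("provenance", "")
    )
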