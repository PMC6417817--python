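"""Candidate-read extraction and canonical k-mer counting.

Because k-mer matching is exact, candidate reads are scanned directly for
indexed k-mers without a realignment step: every length-k window of every
read is canonicalized and looked up in the combined KIR + background
index.  Overlapping windows each count, and the per-(read, gene) indicator
``reads_with_hit`` is kept separately for the read-based normalizers.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ._kmers import (
    MAX_PACKED_K,
    canonical,
    canonical_window_codes,
    encode_sequence,
    kmer_code,
)
from .exceptions import KircallError, ParameterError
from .reference import BackgroundKmerSet, UniqueKmerIndex


@dataclass
class SampleReadSet:
    """Read sequences of one sample (qualities are irrelevant and dropped)."""

    sample_id: str
    reads: list[str]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ParameterError("sample_id must be non-empty")


@dataclass
class KmerCountTable:
    """Occurrence counts of indexed k-mers in one sample.

    ``counts`` maps canonical k-mer -> occurrence count (zero-count k-mers
    may be omitted); ``reads_with_hit`` maps gene -> number of reads
    containing at least one of that gene's k-mers.
    """

    sample_id: str
    k: int
    counts: dict[str, int] = field(default_factory=dict)
    reads_with_hit: dict[str, int] = field(default_factory=dict)
    n_reads: int = 0


def read_sequences(path: str | Path, sample_id: str | None = None) -> SampleReadSet:
    """Load reads from FASTQ or FASTA (plain or gzipped)."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    reads = []
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, fmt):
            reads.append(str(record.seq).upper())
    if sample_id is None:
        sample_id = stem.rsplit(".", 1)[0]
    return SampleReadSet(sample_id=sample_id, reads=reads)


def _parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chr:start-end`` (1-based inclusive coordinates)."""
    try:
        contig, span = region.rsplit(":", 1)
        start_s, end_s = span.replace(",", "").split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ParameterError(f"cannot parse region {region!r}") from exc
    if start < 1 or end < start:
        raise ParameterError(f"invalid region bounds in {region!r}")
    return contig, start, end


def extract_candidate_reads(
    alignment_file: str | Path,
    region: str,
    include_unmapped: bool = True,
    sample_id: str | None = None,
) -> SampleReadSet:
    """Pull read sequences overlapping a region, plus optionally all
    unmapped reads, from a coordinate-sorted indexed BAM/CRAM.

    Secondary and supplementary alignments are skipped, and multiple
    alignments of the same segment collapse to one record keyed by
    (read name, first/second of pair).
    """
    import pysam

    path = Path(alignment_file)
    with pysam.AlignmentFile(str(path)) as af:
        if not af.has_index():
            raise KircallError(f"{path} has no index; sort and index it first")
        contig, start, end = _parse_region(region)
        if contig not in af.references:
            raise KircallError(
                f"contig {contig!r} not in alignment file; available: "
                f"{', '.join(af.references)}"
            )
        seen: dict[tuple[str, bool], str] = {}
        for aln in af.fetch(contig, start - 1, end):
            if aln.is_secondary or aln.is_supplementary:
                continue
            key = (aln.query_name, aln.is_read2)
            seen.setdefault(key, aln.query_sequence or "")
        if include_unmapped:
            for aln in af.fetch(until_eof=True):
                if not aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                key = (aln.query_name, aln.is_read2)
                seen.setdefault(key, aln.query_sequence or "")
    reads = [seq.upper() for seq in seen.values() if seq]
    return SampleReadSet(sample_id=sample_id or path.stem, reads=reads)


# ---------------------------------------------------------------------------
# Counting core
# ---------------------------------------------------------------------------


class _Lookup:
    """Sorted-code lookup over the combined KIR + background k-mer sets."""

    def __init__(self, index: UniqueKmerIndex, background: BackgroundKmerSet | None):
        self.k = index.k
        gene_names: list[str] = []
        kmers: list[str] = []
        gene_of: list[int] = []
        sources = [index.per_gene]
        if background is not None:
            if background.k != index.k:
                raise ParameterError(
                    f"background k={background.k} != index k={index.k}"
                )
            sources.append(background.per_gene)
        for per_gene in sources:
            for gene in per_gene:
                gid = len(gene_names)
                gene_names.append(gene)
                for km in sorted(per_gene[gene]):
                    kmers.append(km)
                    gene_of.append(gid)
        self.gene_names = gene_names
        self.kmers = kmers
        self.gene_of = np.asarray(gene_of, dtype=np.int64)
        self.packed = self.k <= MAX_PACKED_K
        if self.packed:
            codes = np.asarray([kmer_code(km) for km in kmers], dtype=np.int64)
            order = np.argsort(codes)
            self.codes_sorted = codes[order]
            self.order = order
        else:
            self.by_string = {
                km: i for i, km in enumerate(kmers)
            }


def count_kmers(
    reads: SampleReadSet,
    index: UniqueKmerIndex,
    background: BackgroundKmerSet | None = None,
) -> KmerCountTable:
    """Count occurrences of indexed k-mers over every window of every read.

    Pure function of its inputs: overlapping windows each count, matching
    is strand-agnostic via canonical form, and reads shorter than k simply
    contribute no windows.
    """
    lookup = _Lookup(index, background)
    k = lookup.k
    n_kmers = len(lookup.kmers)
    counts = np.zeros(n_kmers, dtype=np.int64)
    n_genes = len(lookup.gene_names)
    reads_with_hit = np.zeros(n_genes, dtype=np.int64)

    if n_kmers and reads.reads:
        if lookup.packed:
            big = "N".join(reads.reads)
            values = encode_sequence(big)
            codes, starts = canonical_window_codes(values, k)
            if codes.size:
                pos = np.searchsorted(lookup.codes_sorted, codes)
                pos_clip = np.minimum(pos, n_kmers - 1)
                hit = lookup.codes_sorted[pos_clip] == codes
                kmer_idx = lookup.order[pos_clip[hit]]
                counts += np.bincount(kmer_idx, minlength=n_kmers)
                # map window start back to its read via the offsets array
                lengths = np.fromiter(
                    (len(r) + 1 for r in reads.reads), dtype=np.int64
                )
                offsets = np.concatenate([[0], np.cumsum(lengths)])
                read_id = np.searchsorted(offsets, starts[hit], side="right") - 1
                pair = read_id * n_genes + lookup.gene_of[kmer_idx]
                uniq = np.unique(pair)
                reads_with_hit += np.bincount(
                    uniq % n_genes, minlength=n_genes
                )
        else:
            for rid, read in enumerate(reads.reads):
                genes_hit: set[int] = set()
                for i in range(len(read) - k + 1):
                    window = read[i : i + k]
                    if "N" in window:
                        continue
                    j = lookup.by_string.get(canonical(window))
                    if j is not None:
                        counts[j] += 1
                        genes_hit.add(int(lookup.gene_of[j]))
                for g in genes_hit:
                    reads_with_hit[g] += 1

    count_map = {
        lookup.kmers[i]: int(counts[i]) for i in np.nonzero(counts)[0]
    }
    rwh = {
        lookup.gene_names[g]: int(reads_with_hit[g]) for g in range(n_genes)
    }
    return KmerCountTable(
        sample_id=reads.sample_id,
        k=k,
        counts=count_map,
        reads_with_hit=rwh,
        n_reads=len(reads.reads),
    )


def add_tables(a: KmerCountTable, b: KmerCountTable) -> KmerCountTable:
    """Sum two count tables from batches of the same sample."""
    if a.k != b.k:
        raise ParameterError(f"cannot add tables with k={a.k} and k={b.k}")
    counts = dict(a.counts)
    for km, c in b.counts.items():
        counts[km] = counts.get(km, 0) + c
    rwh = dict(a.reads_with_hit)
    for g, c in b.reads_with_hit.items():
        rwh[g] = rwh.get(g, 0) + c
    return KmerCountTable(
        sample_id=a.sample_id,
        k=a.k,
        counts=counts,
        reads_with_hit=rwh,
        n_reads=a.n_reads + b.n_reads,
    )


def aggregate_gene_counts(
    table: KmerCountTable, index: UniqueKmerIndex
) -> dict[str, float]:
    """Mean per-k-mer occurrence count for each gene with >=1 unique k-mer.

    Zero-count k-mers are included in the mean; genes with no unique
    k-mers are absent from the output (their copy number is inferred from
    co-segregation instead).
    """
    if table.k != index.k:
        raise ParameterError(f"table k={table.k} != index k={index.k}")
    out: dict[str, float] = {}
    for gene, kmers in index.per_gene.items():
        if not kmers:
            continue
        total = sum(table.counts.get(km, 0) for km in kmers)
        out[gene] = total / len(kmers)
    return out


def kmer_totals(
    table: KmerCountTable,
    index: UniqueKmerIndex,
    background: BackgroundKmerSet,
) -> tuple[int, int]:
    """(KIR total, background total) summed occurrence counts for QC filters."""
    kir = sum(table.counts.get(km, 0) for km in index.all_kmers)
    bg = sum(table.counts.get(km, 0) for km in background.all_kmers)
    return kir, bg


def write_count_table(
    table: KmerCountTable, lookup_gene: Mapping[str, str], path: str | Path
) -> None:
    """Write per-k-mer counts as TSV (columns: kmer, gene, count)."""
    with open(path, "w") as fh:
        fh.write("kmer\tgene\tcount\n")
        for km in sorted(table.counts):
            fh.write(f"{km}\t{lookup_gene.get(km, '?')}\t{table.counts[km]}\n")


def save_table(table: KmerCountTable, path: str | Path) -> None:
    """Serialize a count table to JSON (lossless round-trip)."""
    import json

    payload = {
        "sample_id": table.sample_id,
        "k": table.k,
        "n_reads": table.n_reads,
        "counts": table.counts,
        "reads_with_hit": table.reads_with_hit,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_table(path: str | Path) -> KmerCountTable:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    return KmerCountTable(
        sample_id=payload["sample_id"],
        k=payload["k"],
        counts={k: int(v) for k, v in payload["counts"].items()},
        reads_with_hit={k: int(v) for k, v in payload["reads_with_hit"].items()},
        n_reads=payload["n_reads"],
    )
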