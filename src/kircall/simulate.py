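"""Synthetic cohorts for end-to-end testing of the caller.

The generator emulates the population structure the caller assumes:

* a library of homologous genes sharing a common backbone (so most
  k-mers are non-unique — the core difficulty) with gene-specific
  segments and allelic point variation;
* one gene pair in which the "hidden" gene's alleles are exact prefixes
  of its partner's alleles, so it carries **zero** unique k-mers and can
  only be called through co-segregation;
* diploid genotypes drawn per haplotype from configured gene
  frequencies, with co-segregation built in;
* reads drawn uniformly from each sample's gene copies with lognormal
  per-sample depth variation, uniform base errors and equiprobable
  strands.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._kmers import BASES
from .counting import SampleReadSet
from .exceptions import ConfigError
from .model import CosegRule, GeneCategoryConfig
from .reference import AlleleLibrary

_B = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulatedGene:
    """One gene of the simulated panel.

    ``hap_frequency`` is the probability that a haplotype carries the
    gene.  ``inferred_equal`` genes copy their source's haplotype state
    (and, when ``in_library``, their sequences are prefixes of the
    source's alleles, yielding zero unique k-mers); ``inferred_inverse``
    genes occupy the alternative haplotype slot of their source and have
    no sequence in the library.
    """

    name: str
    category: str  # anchor | high_freq | low_freq | inferred_equal | inferred_inverse
    hap_frequency: float = 1.0
    source: str | None = None
    in_library: bool = True
    shared_prefix_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.category not in (
            "anchor",
            "high_freq",
            "low_freq",
            "inferred_equal",
            "inferred_inverse",
        ):
            raise ConfigError(f"unknown simulated category {self.category!r}")
        if not 0.0 <= self.hap_frequency <= 1.0:
            raise ConfigError("hap_frequency must be in [0, 1]")
        if self.category.startswith("inferred") and self.source is None:
            raise ConfigError(f"inferred gene {self.name} needs a source")


def default_gene_panel() -> tuple[SimulatedGene, ...]:
    """Default 8-gene library panel plus one sequence-free inverse gene.

    Anchors are universally diploid; high-frequency genes segregate at a
    per-haplotype frequency of 0.7 (copy mix ~9/42/49%), low-frequency
    genes at 0.25 (~56/38/6%).  KIR2DS1 co-segregates with KIR3DS1 and
    carries no unique k-mers; KIR2DL3 is the haplotype alternative of
    KIR2DS2.
    """
    return (
        SimulatedGene("KIR3DL3", "anchor"),
        SimulatedGene("KIR3DL2", "anchor"),
        SimulatedGene("KIR2DL1", "high_freq", 0.7),
        SimulatedGene("KIR2DP1", "high_freq", 0.7),
        SimulatedGene("KIR2DS4", "high_freq", 0.7),
        SimulatedGene("KIR2DS2", "low_freq", 0.25),
        SimulatedGene("KIR3DS1", "low_freq", 0.25),
        SimulatedGene("KIR2DS1", "inferred_equal", source="KIR3DS1"),
        SimulatedGene(
            "KIR2DL3", "inferred_inverse", source="KIR2DS2", in_library=False
        ),
    )


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe a mid-sized exome cohort: 500 samples at 30x mean
    haploid depth with a 30% lognormal depth CV and a 0.1% uniform base
    error rate; 1 kb genes sharing 70% of their length as a common
    backbone, three alleles per gene differing by five substitutions; a
    20-gene background panel for depth normalization.
    """

    seed: int = 0
    genes: tuple[SimulatedGene, ...] = field(default_factory=default_gene_panel)
    alleles_per_gene: int = 3
    allele_length: int = 1000
    homology_fraction: float = 0.7
    substitutions_per_allele: int = 5
    n_background_genes: int = 20
    background_gene_length: int = 600
    n_samples: int = 500
    read_length: int = 100
    mean_depth: float = 30.0
    depth_cv: float = 0.3
    base_error_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.homology_fraction < 1.0:
            raise ConfigError("homology_fraction must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if not 0.0 <= self.base_error_rate <= 0.1:
            raise ConfigError("base_error_rate must be in [0, 0.1]")
        if self.read_length > min(self.allele_length, self.background_gene_length):
            raise ConfigError("read_length must not exceed gene length")
        specific = self.allele_length - round(
            self.homology_fraction * self.allele_length
        )
        if specific < 1:
            raise ConfigError(
                "homology_fraction leaves no room for a gene-specific segment"
            )
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate gene names in panel")
        by_name = {g.name: g for g in self.genes}
        for g in self.genes:
            if g.source is not None and g.source not in by_name:
                raise ConfigError(f"{g.name}: unknown source {g.source}")

    # Seed streams for the independent stages.
    def _seeds(self) -> dict[str, np.random.SeedSequence]:
        root = np.random.SeedSequence(self.seed)
        lib, bg, cohort, reads = root.spawn(4)
        return {"library": lib, "background": bg, "cohort": cohort, "reads": reads}

    def category_config(self) -> GeneCategoryConfig:
        """Caller-side category/rule configuration matching this panel."""
        category = {}
        rules = []
        for g in self.genes:
            if g.category == "anchor":
                category[g.name] = "anchor"
            elif g.category == "high_freq":
                category[g.name] = "high_freq_non_anchor"
            elif g.category == "low_freq":
                category[g.name] = "low_freq_non_anchor"
            else:
                category[g.name] = "inferred"
                mode = "sum" if g.category == "inferred_equal" else "inverse"
                rules.append(CosegRule(g.name, (g.source,), mode=mode))
        return GeneCategoryConfig(category=category, coseg_rules=tuple(rules))


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort."""

    copy_numbers: pd.DataFrame  # samples x genes, true integer copies
    depths: pd.Series  # per-sample haploid depth
    library_checksum: str = ""

    def write_tsv(self, path) -> None:
        out = self.copy_numbers.copy()
        out["depth"] = self.depths
        out.to_csv(path, sep="\t", index_label="sample")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _B[codes].tobytes().decode("ascii")


def _mutate(
    rng: np.random.Generator, base: np.ndarray, n_subs: int
) -> np.ndarray:
    out = base.copy()
    if n_subs > 0 and out.size > 0:
        pos = rng.choice(out.size, size=min(n_subs, out.size), replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=pos.size)) % 4
    return out


def simulate_allele_library(config: SimulationConfig) -> AlleleLibrary:
    """Generate the homologous multi-allele gene library.

    All genes share one random backbone over ``homology_fraction`` of
    their length, followed by a gene-specific segment; alleles differ by
    random point substitutions.  ``inferred_equal`` genes are built as
    exact prefixes of their source's alleles (backbone plus a shared
    fraction of the source-specific segment), which guarantees they have
    no unique k-mers of their own.
    """
    rng = np.random.default_rng(config._seeds()["library"])
    L = config.allele_length
    backbone_len = round(config.homology_fraction * L)
    backbone = _random_seq(rng, backbone_len)

    allele_arrays: dict[str, list[np.ndarray]] = {}
    ordered = [g for g in config.genes if g.in_library]
    # sources must exist before prefix-sharing targets
    for g in sorted(ordered, key=lambda g: g.category == "inferred_equal"):
        if g.category == "inferred_equal":
            source_alleles = allele_arrays[g.source]
            spec_len = source_alleles[0].size - backbone_len
            keep = backbone_len + round(g.shared_prefix_fraction * spec_len)
            allele_arrays[g.name] = [a[:keep].copy() for a in source_alleles]
        else:
            specific = _random_seq(rng, L - backbone_len)
            ref = np.concatenate([backbone, specific])
            alleles = [ref]
            for _ in range(config.alleles_per_gene - 1):
                alleles.append(
                    _mutate(rng, ref, config.substitutions_per_allele)
                )
            allele_arrays[g.name] = alleles

    genes = {
        g.name: [
            (f"{i + 1:03d}", _codes_to_str(arr))
            for i, arr in enumerate(allele_arrays[g.name])
        ]
        for g in ordered
    }
    return AlleleLibrary(genes, name=f"sim-seed{config.seed}")


def simulate_background_library(config: SimulationConfig) -> AlleleLibrary:
    """Random unrelated single-allele genes for the normalization panel."""
    rng = np.random.default_rng(config._seeds()["background"])
    genes = {
        f"BG{i + 1:03d}": [
            ("001", _codes_to_str(_random_seq(rng, config.background_gene_length)))
        ]
        for i in range(config.n_background_genes)
    }
    return AlleleLibrary(genes, name=f"sim-bg-seed{config.seed}")


def simulate_cohort(
    config: SimulationConfig, library: AlleleLibrary | None = None
) -> TruthSet:
    """Draw diploid genotypes and per-sample depths.

    Each sample draws two haplotypes; gene presence per haplotype is
    Bernoulli(hap_frequency), anchors are always present, and inferred
    genes copy (or invert) their source's haplotype state, so the truth
    satisfies the co-segregation rules by construction.
    """
    rng = np.random.default_rng(config._seeds()["cohort"])
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    hap: dict[str, np.ndarray] = {}
    for g in config.genes:
        if g.category == "anchor":
            hap[g.name] = np.ones((n, 2), dtype=np.int64)
        elif g.category in ("high_freq", "low_freq"):
            hap[g.name] = (
                rng.random((n, 2)) < g.hap_frequency
            ).astype(np.int64)
    for g in config.genes:
        if g.category == "inferred_equal":
            hap[g.name] = hap[g.source].copy()
        elif g.category == "inferred_inverse":
            hap[g.name] = 1 - hap[g.source]

    copies = pd.DataFrame(
        {name: arr.sum(axis=1) for name, arr in hap.items()}, index=samples
    )[[g.name for g in config.genes]]

    sigma = np.sqrt(np.log(1 + config.depth_cv**2))
    mu = np.log(config.mean_depth) - sigma**2 / 2
    depths = pd.Series(
        rng.lognormal(mu, sigma, size=n), index=samples, name="depth"
    )
    checksum = library.checksum() if library is not None else ""
    return TruthSet(copy_numbers=copies, depths=depths, library_checksum=checksum)


def _simulate_copy_reads(
    rng: np.random.Generator,
    seq: np.ndarray,
    depth: float,
    read_length: int,
) -> np.ndarray | None:
    """Read matrix (n_reads x read_length base codes) for one gene copy."""
    L = seq.size
    n_reads = rng.poisson(depth * L / read_length)
    if n_reads == 0:
        return None
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    return seq[starts[:, None] + np.arange(read_length)[None, :]]


def simulate_sample_reads(
    config: SimulationConfig,
    library: AlleleLibrary,
    truth: TruthSet,
    sample_id: str,
    background: AlleleLibrary | None = None,
    seed_sequence: np.random.SeedSequence | None = None,
    depth: float | None = None,
) -> SampleReadSet:
    """Reads of one sample: uniform draws from its gene copies, random
    strand, independent base errors."""
    if seed_sequence is None:
        i = list(truth.copy_numbers.index).index(sample_id)
        seed_sequence = config._seeds()["reads"].spawn(config.n_samples)[i]
    rng = np.random.default_rng(seed_sequence)
    if depth is None:
        depth = float(truth.depths.loc[sample_id])
    R = config.read_length

    encoded: dict[str, list[np.ndarray]] = {}
    for lib in (library, background):
        if lib is None:
            continue
        for gene, alleles in lib.genes.items():
            encoded[gene] = [
                np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, seq in alleles
            ]
    # back to 0..3 codes
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    encoded = {g: [lut[a] for a in arrs] for g, arrs in encoded.items()}

    blocks: list[np.ndarray] = []
    row = truth.copy_numbers.loc[sample_id]
    for gene, arrs in encoded.items():
        n_copies = int(row[gene]) if gene in row.index else 2  # background: diploid
        for _ in range(n_copies):
            allele = arrs[rng.integers(0, len(arrs))]
            block = _simulate_copy_reads(rng, allele, depth, R)
            if block is not None:
                blocks.append(block)
    if not blocks:
        return SampleReadSet(sample_id=sample_id, reads=[])
    reads = np.concatenate(blocks, axis=0)

    # base errors
    if config.base_error_rate > 0:
        n_err = rng.binomial(reads.size, config.base_error_rate)
        if n_err:
            flat = rng.choice(reads.size, size=n_err, replace=False)
            reads.reshape(-1)[flat] = (
                reads.reshape(-1)[flat] + rng.integers(1, 4, size=n_err)
            ) % 4

    # equiprobable strands
    flip = rng.random(reads.shape[0]) < 0.5
    reads[flip] = (3 - reads[flip])[:, ::-1]

    ascii_reads = _B[reads]
    return SampleReadSet(
        sample_id=sample_id,
        reads=[ascii_reads[i].tobytes().decode("ascii") for i in range(reads.shape[0])],
    )


def simulate_reads(
    config: SimulationConfig,
    library: AlleleLibrary,
    truth: TruthSet,
    background: AlleleLibrary | None = None,
    depths: pd.Series | None = None,
) -> Iterator[SampleReadSet]:
    """Yield one :class:`SampleReadSet` per sample (memory-friendly).

    ``depths`` optionally overrides the truth depths (e.g. to impose a
    fixed depth range when studying normalization).
    """
    children = config._seeds()["reads"].spawn(config.n_samples)
    for i, sample_id in enumerate(truth.copy_numbers.index):
        depth = None if depths is None else float(depths.loc[sample_id])
        yield simulate_sample_reads(
            config,
            library,
            truth,
            sample_id,
            background=background,
            seed_sequence=children[i],
            depth=depth,
        )


def write_fastq(reads: SampleReadSet, path) -> None:
    """Plain or gzipped FASTQ with constant quality."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads.reads):
            fh.write(f"@{reads.sample_id}:{i}\n{seq}\n+\n{'I' * len(seq)}\n")
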