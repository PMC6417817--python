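"""Depth normalization, normalization-method selection and cohort QC.

Per-gene aggregate counts scale with sequencing depth, so each sample is
divided by a normalizer derived from the background gene panel.  Four
normalizers are supported: {mean, median} of the per-background-gene
statistic, where the statistic is either the gene's mean per-k-mer
occurrence count or its reads-with-hit count.  The method and the k-mer
length are chosen by minimizing the population variance of an anchor gene
(KIR3DL3 by default) that is diploid in nearly everyone: the better the
depth correction, the tighter its frequency distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import KmerCountTable, aggregate_gene_counts, kmer_totals
from .exceptions import NormalizationError, ParameterError
from .reference import BackgroundKmerSet, UniqueKmerIndex

ANCHOR_GENE = "KIR3DL3"


@dataclass(frozen=True)
class NormalizationMethod:
    """One of the four depth normalizers: {mean, median} x {k-mer
    occurrences, reads with >=1 hit} over the background gene panel."""

    statistic: str  # 'mean' | 'median'
    unit: str  # 'kmer_occurrences' | 'reads_with_hit'

    def __post_init__(self) -> None:
        if self.statistic not in ("mean", "median"):
            raise ParameterError(f"unknown statistic {self.statistic!r}")
        if self.unit not in ("kmer_occurrences", "reads_with_hit"):
            raise ParameterError(f"unknown unit {self.unit!r}")

    @property
    def label(self) -> str:
        return f"{self.statistic}/{self.unit}"


MEAN_KMER = NormalizationMethod("mean", "kmer_occurrences")
MEAN_READS = NormalizationMethod("mean", "reads_with_hit")
MEDIAN_KMER = NormalizationMethod("median", "kmer_occurrences")
MEDIAN_READS = NormalizationMethod("median", "reads_with_hit")
ALL_METHODS: tuple[NormalizationMethod, ...] = (
    MEAN_KMER,
    MEAN_READS,
    MEDIAN_KMER,
    MEDIAN_READS,
)
#: Shipped default: k=30 with the mean per-k-mer background count.
DEFAULT_METHOD = MEAN_KMER
DEFAULT_K = 30


def background_gene_statistics(
    table: KmerCountTable, background: BackgroundKmerSet, unit: str
) -> dict[str, float]:
    """Per-background-gene statistic used by the normalizers."""
    out: dict[str, float] = {}
    for gene, kmers in background.per_gene.items():
        if unit == "kmer_occurrences":
            if not kmers:
                continue
            out[gene] = sum(table.counts.get(km, 0) for km in kmers) / len(kmers)
        else:
            out[gene] = float(table.reads_with_hit.get(gene, 0))
    return out


def compute_normalizer(
    table: KmerCountTable,
    background: BackgroundKmerSet,
    method: NormalizationMethod = DEFAULT_METHOD,
) -> float:
    """Strictly positive depth normalizer for one sample."""
    if not background.per_gene:
        raise ParameterError("background set is empty")
    stats = background_gene_statistics(table, background, method.unit)
    if not stats:
        raise NormalizationError("background set has no usable genes")
    values = list(stats.values())
    norm = float(np.mean(values)) if method.statistic == "mean" else float(median(values))
    if norm <= 0:
        raise NormalizationError(
            f"sample {table.sample_id} has no background coverage"
        )
    return norm


def normalize(aggregates: Mapping[str, float], normalizer: float) -> dict[str, float]:
    """Divide per-gene aggregate counts by the sample's normalizer."""
    if normalizer <= 0:
        raise ParameterError("normalizer must be positive")
    return {gene: value / normalizer for gene, value in aggregates.items()}


def frequency_matrix(
    tables: Sequence[KmerCountTable],
    index: UniqueKmerIndex,
    background: BackgroundKmerSet,
    method: NormalizationMethod = DEFAULT_METHOD,
) -> pd.DataFrame:
    """Samples x genes normalized mean k-mer frequency matrix."""
    rows = {}
    for table in tables:
        norm = compute_normalizer(table, background, method)
        rows[table.sample_id] = normalize(aggregate_gene_counts(table, index), norm)
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    out.attrs["k"] = index.k
    out.attrs["method"] = method.label
    return out


@dataclass
class NormalizationEvaluation:
    """Anchor-gene variances per (k, method), the strict argmin and the
    parsimony-rule selection."""

    variances: pd.DataFrame  # index: k, columns: method label
    best_k: int
    best_method: NormalizationMethod
    argmin_k: int
    argmin_method: NormalizationMethod
    anchor_gene: str
    n_se: float


def evaluate_normalization(
    tables_by_k: Mapping[int, Sequence[KmerCountTable]],
    indexes_by_k: Mapping[int, UniqueKmerIndex],
    backgrounds_by_k: Mapping[int, BackgroundKmerSet],
    anchor_gene: str = ANCHOR_GENE,
    methods: Sequence[NormalizationMethod] = ALL_METHODS,
    n_se: float = 2.0,
) -> NormalizationEvaluation:
    """Sweep (k, method) and select a combination by anchor-gene variance.

    Frequencies are rescaled to unit cohort mean before taking the
    variance so that units with different absolute scales are compared on
    one footing (the variance of the mean-one vector is the squared
    coefficient of variation).  Variance is the unbiased sample variance.

    Two answers are reported.  ``argmin_k``/``argmin_method`` is the
    strict cell-wise minimum (exact ties broken toward larger k, which
    retains more coverage of low-frequency genes).  ``best_k``/
    ``best_method`` is the headline *selection*, which applies a
    one-standard-error-style parsimony rule: among all cells whose
    variance is within ``n_se`` standard errors of the minimum (the
    relative SE of a sample variance is ~sqrt(2/(n-1))), prefer the
    earliest-listed method and then the largest k.  Candidate normalizers
    are often statistically indistinguishable, in which case the strict
    argmin is noise; the parsimony rule keeps the simplest statistic and
    the k with the best coverage of low-frequency genes.
    """
    ks = sorted(tables_by_k)
    if not ks:
        raise ParameterError("no candidate k values")
    for k in ks:
        if len(tables_by_k[k]) < 2:
            raise ParameterError("need >=2 samples to evaluate normalization")
        if not indexes_by_k[k].per_gene.get(anchor_gene):
            raise ParameterError(
                f"anchor gene {anchor_gene} has no unique k-mers at k={k}"
            )

    table = pd.DataFrame(index=ks, columns=[m.label for m in methods], dtype=float)
    for k in ks:
        index = indexes_by_k[k]
        background = backgrounds_by_k[k]
        aggs = [aggregate_gene_counts(t, index)[anchor_gene] for t in tables_by_k[k]]
        for m in methods:
            norms = [compute_normalizer(t, background, m) for t in tables_by_k[k]]
            freq = np.asarray(aggs) / np.asarray(norms)
            mean = freq.mean()
            scaled = freq / mean if mean > 0 else freq
            table.loc[k, m.label] = float(np.var(scaled, ddof=1))

    # strict argmin: smallest variance; exact ties to larger k, then to the
    # earlier-listed method
    candidates = [
        (table.loc[k, m.label], -k, mi, k, m)
        for mi, m in enumerate(methods)
        for k in ks
    ]
    _, _, _, argmin_k, argmin_method = min(candidates, key=lambda c: c[:3])

    # parsimony selection within the noise envelope of the minimum
    n = min(len(tables_by_k[k]) for k in ks)
    envelope = float(table.min().min()) * (1 + n_se * np.sqrt(2 / max(n - 1, 1)))
    best_method = next(
        (m for m in methods if table[m.label].min() <= envelope), argmin_method
    )
    in_env = [k for k in ks if table.loc[k, best_method.label] <= envelope]
    best_k = max(in_env) if in_env else argmin_k

    return NormalizationEvaluation(
        variances=table,
        best_k=int(best_k),
        best_method=best_method,
        argmin_k=int(argmin_k),
        argmin_method=argmin_method,
        anchor_gene=anchor_gene,
        n_se=n_se,
    )


def coverage_totals(
    tables: Sequence[KmerCountTable],
    index: UniqueKmerIndex,
    background: BackgroundKmerSet,
) -> pd.DataFrame:
    """Per-sample summed occurrence counts over the KIR and background sets."""
    rows = {}
    for t in tables:
        kir, bg = kmer_totals(t, index, background)
        rows[t.sample_id] = {"kir_total": kir, "background_total": bg}
    return pd.DataFrame.from_dict(rows, orient="index")


def apply_coverage_filters(
    totals: pd.DataFrame,
    random_gene_min: int = 40_000,
    kir_min: int = 20_000,
) -> tuple[list[str], pd.DataFrame]:
    """Cohort coverage QC.

    A sample is retained iff its background total is >= ``random_gene_min``
    AND its KIR total is >= ``kir_min`` (strict less-than exclusion).
    Returns the retained sample ids and a per-exclusion report naming the
    failing criterion.
    """
    retained: list[str] = []
    report_rows = []
    for sample, row in totals.iterrows():
        bg, kir = row["background_total"], row["kir_total"]
        reasons = []
        if bg < random_gene_min:
            reasons.append("background")
        if kir < kir_min:
            reasons.append("kir")
        if reasons:
            report_rows.append(
                {
                    "sample": sample,
                    "background_total": bg,
                    "kir_total": kir,
                    "reason": "+".join(reasons),
                }
            )
        else:
            retained.append(sample)
    report = pd.DataFrame(
        report_rows, columns=["sample", "background_total", "kir_total", "reason"]
    )
    return retained, report


def embed_background_profiles(
    tables: Sequence[KmerCountTable],
    background: BackgroundKmerSet,
    perplexity: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Optional diagnostic: 2-D t-SNE embedding of per-sample background
    k-mer frequency profiles, useful for spotting capture-kit batch
    structure.  Purely visual; plays no role in calling."""
    from sklearn.manifold import TSNE

    kmers = sorted(background.all_kmers)
    mat = np.zeros((len(tables), len(kmers)))
    for i, t in enumerate(tables):
        row = np.asarray([t.counts.get(km, 0) for km in kmers], dtype=float)
        total = row.sum()
        mat[i] = row / total if total > 0 else row
    emb = TSNE(
        n_components=2,
        perplexity=min(perplexity, max(2.0, (len(tables) - 1) / 3)),
        random_state=seed,
        init="pca",
    ).fit_transform(mat)
    return pd.DataFrame(
        emb, index=[t.sample_id for t in tables], columns=["tsne1", "tsne2"]
    )
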