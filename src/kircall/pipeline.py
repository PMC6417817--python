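"""End-to-end cohort workflows: count -> QC -> normalize -> call.

These helpers glue the per-module operations into the standard cohort
pipeline and back the command-line interface, the acceptance experiments
and the simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .counting import KmerCountTable, SampleReadSet, count_kmers
from .exceptions import ParameterError
from .model import (
    CopyNumberMatrix,
    GeneCategoryConfig,
    KirCopyNumberModel,
    KirCopyNumberResults,
    THREE_PLUS,
)
from .normalization import (
    DEFAULT_METHOD,
    NormalizationMethod,
    apply_coverage_filters,
    coverage_totals,
    frequency_matrix,
)
from .reference import (
    AlleleLibrary,
    BackgroundKmerSet,
    UniqueKmerIndex,
    extract_unique_kmers,
    select_background_kmers,
)
from .simulate import (
    SimulationConfig,
    TruthSet,
    simulate_allele_library,
    simulate_background_library,
    simulate_cohort,
    simulate_reads,
)


def count_cohort(
    read_sets: Iterable[SampleReadSet],
    index: UniqueKmerIndex,
    background: BackgroundKmerSet | None = None,
) -> list[KmerCountTable]:
    return [count_kmers(rs, index, background) for rs in read_sets]


@dataclass
class CohortCallResult:
    """Everything produced by a cohort calling run."""

    frequencies: pd.DataFrame
    results: KirCopyNumberResults
    retained: list[str]
    qc_report: pd.DataFrame

    @property
    def copy_numbers(self) -> CopyNumberMatrix:
        return self.results.copy_numbers


def call_cohort(
    tables: Sequence[KmerCountTable],
    index: UniqueKmerIndex,
    background: BackgroundKmerSet,
    config: GeneCategoryConfig,
    method: NormalizationMethod = DEFAULT_METHOD,
    *,
    apply_filters: bool = True,
    random_gene_min: int = 40_000,
    kir_min: int = 20_000,
    **model_kwargs,
) -> CohortCallResult:
    """Standard cohort pipeline from count tables to copy-number calls."""
    if apply_filters:
        totals = coverage_totals(tables, index, background)
        retained, report = apply_coverage_filters(
            totals, random_gene_min=random_gene_min, kir_min=kir_min
        )
        kept = [t for t in tables if t.sample_id in set(retained)]
    else:
        retained = [t.sample_id for t in tables]
        report = pd.DataFrame(
            columns=["sample", "background_total", "kir_total", "reason"]
        )
        kept = list(tables)
    if not kept:
        raise ParameterError("no samples pass the coverage filters")
    freqs = frequency_matrix(kept, index, background, method)
    model = KirCopyNumberModel(freqs, config, **model_kwargs)
    results = model.fit()
    return CohortCallResult(
        frequencies=freqs, results=results, retained=retained, qc_report=report
    )


# ---------------------------------------------------------------------------
# Simulation studies
# ---------------------------------------------------------------------------


@dataclass
class SimulationStudy:
    """A full simulated cohort run with its ground truth."""

    config: SimulationConfig
    library: AlleleLibrary
    background_library: AlleleLibrary
    index: UniqueKmerIndex
    background: BackgroundKmerSet
    truth: TruthSet
    tables: list[KmerCountTable]
    call: CohortCallResult

    @property
    def copy_numbers(self) -> CopyNumberMatrix:
        return self.call.copy_numbers


def run_simulation_study(
    config: SimulationConfig,
    k: int = 30,
    max_background_kmers: int = 100,
    apply_filters: bool = True,
    depths: pd.Series | None = None,
    **model_kwargs,
) -> SimulationStudy:
    """Simulate a cohort and run the full pipeline against it."""
    library = simulate_allele_library(config)
    bg_library = simulate_background_library(config)
    index = extract_unique_kmers(library, k)
    background = select_background_kmers(
        bg_library,
        index,
        kir_library=library,
        k=k,
        max_per_gene=max_background_kmers,
        seed=config.seed,
    )
    truth = simulate_cohort(config, library)
    tables = count_cohort(
        simulate_reads(config, library, truth, background=bg_library, depths=depths),
        index,
        background,
    )
    call = call_cohort(
        tables,
        index,
        background,
        config.category_config(),
        apply_filters=apply_filters,
        **model_kwargs,
    )
    return SimulationStudy(
        config=config,
        library=library,
        background_library=bg_library,
        index=index,
        background=background,
        truth=truth,
        tables=tables,
        call=call,
    )


@dataclass
class TruthComparison:
    """Per-cell agreement between calls and simulation truth."""

    measured_accuracy: float  # fraction of non-excluded measured calls correct
    excluded_fraction: float  # fraction of cells excluded (measured + inferred)
    inferred_accuracy: float  # fraction of non-excluded inferred calls correct
    inferred_accuracy_sources_correct: float  # ... restricted to cells whose
    # source-gene calls all match truth
    n_measured: int
    n_inferred: int


def compare_to_truth(
    matrix: CopyNumberMatrix,
    truth: TruthSet,
    config: GeneCategoryConfig,
) -> TruthComparison:
    """Score calls against the generator's ground truth ("3+" matches any
    true copy number >= 3)."""
    truth_sub = truth.copy_numbers.loc[
        matrix.samples, [g for g in matrix.genes if g in truth.copy_numbers.columns]
    ].clip(upper=THREE_PLUS)
    measured_genes = [
        g for g in truth_sub.columns if config.category.get(g) != "inferred"
    ]
    inferred_genes = [
        g for g in truth_sub.columns if config.category.get(g) == "inferred"
    ]
    rules = {r.target: r for r in config.coseg_rules}

    calls = matrix.calls

    def _score(genes: list[str]) -> tuple[int, int, int]:
        ok = total = excl = 0
        for g in genes:
            c = calls[g]
            t = truth_sub[g]
            mask = c.notna()
            excl += int((~mask).sum())
            total += int(mask.sum())
            ok += int((c[mask] == t[mask]).sum())
        return ok, total, excl

    m_ok, m_total, m_excl = _score(measured_genes)
    i_ok, i_total, i_excl = _score(inferred_genes)

    # inferred cells whose sources are themselves correct
    src_ok = src_total = 0
    for g in inferred_genes:
        rule = rules.get(g)
        if rule is None:
            continue
        c = calls[g]
        mask = c.notna()
        for s in rule.sources:
            mask &= calls[s].notna() & (calls[s] == truth_sub[s])
        src_total += int(mask.sum())
        src_ok += int((c[mask] == truth_sub[g][mask]).sum())

    n_cells = len(matrix.samples) * len(truth_sub.columns)
    return TruthComparison(
        measured_accuracy=m_ok / m_total if m_total else float("nan"),
        excluded_fraction=(m_excl + i_excl) / n_cells if n_cells else float("nan"),
        inferred_accuracy=i_ok / i_total if i_total else float("nan"),
        inferred_accuracy_sources_correct=(
            src_ok / src_total if src_total else float("nan")
        ),
        n_measured=m_total,
        n_inferred=i_total,
    )
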