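"""Population-density copy-number model for the KIR cluster.

The central idea: across a large cohort, a gene's normalized unique-k-mer
frequency is proportional to its germline copy number, so the population
distribution of that frequency is a mixture with one mode per copy-number
state.  A Gaussian kernel density estimate of each gene's frequencies is
segmented into copy-number intervals using category-specific rules:

* **anchor** genes (diploid in nearly everyone) — the highest peak is copy
  2; its measured width sets the 1-copy and 3+ boundaries;
* **high-frequency non-anchor** genes — three peaks map to 0, 1 and 2
  copies with boundaries at the intervening density valleys;
* **low-frequency non-anchor** genes — the left-most (highest) peak is 0
  copies, the second 1 copy, and the inter-peak distance is extrapolated
  to place the 2 and 3+ boundaries.

Samples falling within a small margin of any boundary (the 1/2-copy
boundary divided by 50, by default) are excluded for that gene.  Genes
without unique k-mers are filled in afterwards from co-segregation rules.

The model is fitted cohort-wide: with fewer than ~50 samples the density
modes are not identifiable, so single-sample calling is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .exceptions import (
    ConfigError,
    DensityError,
    KircallWarning,
    ParameterError,
    ThresholdError,
)

CATEGORIES = ("anchor", "high_freq_non_anchor", "low_freq_non_anchor", "inferred")

#: Copy-number value encoding "3 or more".
THREE_PLUS = 3

MEASURED = "measured"
INFERRED = "inferred"
INFERRED_CLAMPED = "inferred_clamped"
EXCLUDED = "excluded"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CosegRule:
    """Copy number of ``target`` derived from measured source genes.

    ``mode='sum'``: target copies = sum of source copies.
    ``mode='inverse'``: target copies = baseline - sum of source copies,
    clamped below at 0 (the two genes occupy the same haplotype slot, so
    each haplotype carries one or the other).
    """

    target: str
    sources: tuple[str, ...]
    mode: str = "sum"
    baseline: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("sum", "inverse"):
            raise ConfigError(f"unknown co-segregation mode {self.mode!r}")
        if not self.sources:
            raise ConfigError(f"rule for {self.target} has no source genes")


#: Canonical KIR co-segregation rules: 2DS1 tracks 3DS1, 2DL2 tracks 2DS2,
#: 3DL1 tracks 2DS4, 2DL5A is the combined total of 2DS3 and 2DS5, and
#: 2DL3 varies inversely with 2DS2.
DEFAULT_COSEG_RULES: tuple[CosegRule, ...] = (
    CosegRule("KIR2DS1", ("KIR3DS1",)),
    CosegRule("KIR2DL2", ("KIR2DS2",)),
    CosegRule("KIR3DL1", ("KIR2DS4",)),
    CosegRule("KIR2DL5A", ("KIR2DS3", "KIR2DS5")),
    CosegRule("KIR2DL3", ("KIR2DS2",), mode="inverse", baseline=2),
)


@dataclass
class GeneCategoryConfig:
    """Gene categories, modal-ploidy priors and co-segregation rules."""

    category: dict[str, str]
    prior_modal_ploidy: dict[str, int] = field(default_factory=dict)
    coseg_rules: tuple[CosegRule, ...] = ()

    def __post_init__(self) -> None:
        for gene, cat in self.category.items():
            if cat not in CATEGORIES:
                raise ConfigError(f"gene {gene}: unknown category {cat!r}")
        targets = [r.target for r in self.coseg_rules]
        if len(targets) != len(set(targets)):
            raise ConfigError("a gene is the target of more than one rule")
        for gene, cat in self.category.items():
            if cat == "inferred" and gene not in targets:
                raise ConfigError(
                    f"inferred gene {gene} is not the target of any rule"
                )

    def modal_ploidy(self, gene: str) -> int:
        if gene in self.prior_modal_ploidy:
            return self.prior_modal_ploidy[gene]
        defaults = {"anchor": 2, "high_freq_non_anchor": 2, "low_freq_non_anchor": 0}
        return defaults.get(self.category.get(gene, ""), 2)

    @classmethod
    def default_kir(cls) -> "GeneCategoryConfig":
        """Default full-KIR configuration.

        KIR2DL2 is sometimes grouped with the anchors, but it is also the
        target of the KIR2DS2 co-segregation rule; this default treats it
        as inferred and leaves the alternative to user configuration.
        """
        category = {
            "KIR3DL3": "anchor",
            "KIR3DP1": "anchor",
            "KIR3DL2": "anchor",
            "KIR2DP1": "high_freq_non_anchor",
            "KIR2DL1": "high_freq_non_anchor",
            "KIR2DS4": "high_freq_non_anchor",
            "KIR2DL5": "high_freq_non_anchor",
            "KIR2DS3": "low_freq_non_anchor",
            "KIR2DS2": "low_freq_non_anchor",
            "KIR2DS5": "low_freq_non_anchor",
            "KIR3DS1": "low_freq_non_anchor",
            "KIR2DS1": "inferred",
            "KIR2DL2": "inferred",
            "KIR3DL1": "inferred",
            "KIR2DL5A": "inferred",
            "KIR2DL3": "inferred",
        }
        return cls(category=category, coseg_rules=DEFAULT_COSEG_RULES)


# ---------------------------------------------------------------------------
# Density estimation and peak calling
# ---------------------------------------------------------------------------


@dataclass
class PopulationDensity:
    """Gaussian-kernel density of one gene's cohort frequencies.

    Mass is reflected at zero (frequencies are non-negative), so the
    trapezoidal integral over the grid stays ~1 even for genes with a
    point mass of zero-copy samples at the origin.
    """

    gene: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, robustified with the IQR."""
    n = values.size
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not spread_candidates:
        # degenerate (point mass): fall back to a sliver of the scale
        scale = max(abs(float(values[0])), 1.0)
        return 1e-3 * scale
    return 0.9 * min(spread_candidates) * n ** (-1 / 5)


def estimate_density(
    frequencies: Sequence[float] | np.ndarray,
    gene: str = "",
    bandwidth: float | None = None,
    grid_points: int = 512,
    min_samples: int = 50,
) -> PopulationDensity:
    """Gaussian KDE of a gene's cohort frequencies on a fixed grid.

    The grid spans [0, 1.1 x max frequency]; the kernel mass that would
    fall below zero is reflected back.  Deterministic given its inputs.
    """
    values = np.asarray(frequencies, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_samples:
        raise DensityError(
            f"{values.size} samples for gene {gene or '?'}: population "
            f"density needs >= {min_samples} samples (cohort-level use only)"
        )
    if np.any(values < 0):
        raise ParameterError("frequencies must be non-negative")
    h = bandwidth if bandwidth is not None else silverman_bandwidth(values)
    if h <= 0:
        raise ParameterError("bandwidth must be positive")
    upper = float(values.max()) * 1.1
    if upper <= 0:
        upper = max(10 * h, 1e-6)
    grid = np.linspace(0.0, upper, grid_points)
    if bandwidth is None:
        # an automatic bandwidth narrower than the grid spacing would make
        # the trapezoidal mass unreliable
        h = max(h, float(grid[1] - grid[0]))
    # direct Gaussian KDE with reflection at 0
    z = (grid[:, None] - values[None, :]) / h
    zr = (grid[:, None] + values[None, :]) / h
    kernel = np.exp(-0.5 * z**2) + np.exp(-0.5 * zr**2)
    density = kernel.sum(axis=1) / (values.size * h * np.sqrt(2 * np.pi))
    return PopulationDensity(gene=gene, grid=grid, density=density, bandwidth=h)


@dataclass(frozen=True)
class Peak:
    location: float
    height: float
    grid_index: int


def find_peaks_valleys(
    density: PopulationDensity, min_prominence: float = 0.02
) -> tuple[list[Peak], list[float]]:
    """Density peaks above a prominence floor and the valleys between them.

    ``min_prominence`` is a fraction of the maximum density.  Peaks at the
    grid edges count (the zero-copy mode of a low-frequency gene sits at
    the origin).  Valleys are the minimum-density grid points between
    consecutive retained peaks.  Both lists are ordered by location.
    """
    d = density.density
    floor = min_prominence * float(d.max())
    if not np.any(d > 0):
        raise DensityError(f"degenerate density for gene {density.gene or '?'}")
    pad = float(d.min()) - 1.0  # lets edge maxima register as peaks
    padded = np.concatenate([[pad], d, [pad]])
    idx, _ = _scipy_find_peaks(padded, prominence=floor)
    idx = idx - 1
    if idx.size == 0:
        raise DensityError(f"degenerate density for gene {density.gene or '?'}")
    peaks = [Peak(float(density.grid[i]), float(d[i]), int(i)) for i in idx]
    valleys: list[float] = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        between = slice(a.grid_index + 1, b.grid_index)
        if between.stop <= between.start:
            valleys.append(float((a.location + b.location) / 2))
            continue
        j = int(np.argmin(d[between])) + between.start
        valleys.append(float(density.grid[j]))
    return peaks, valleys


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------


@dataclass
class ThresholdSet:
    """Ascending frequency cutoffs mapping intervals to copy numbers.

    ``labels`` has one entry per interval (``len(cutoffs) + 1``) and is
    non-decreasing; ``exclusion_margin`` is the no-call half-width around
    every cutoff (1/2-copy boundary divided by the exclusion divisor).
    """

    gene: str
    cutoffs: np.ndarray
    labels: list[int]
    exclusion_margin: float

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        if len(self.labels) != self.cutoffs.size + 1:
            raise ConfigError("labels must have one entry per interval")
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ConfigError(f"cutoffs not strictly ascending for {self.gene}")
        if any(b < a for a, b in zip(self.labels[:-1], self.labels[1:])):
            raise ConfigError(f"labels not non-decreasing for {self.gene}")
        if self.exclusion_margin <= 0:
            raise ConfigError("exclusion_margin must be positive")

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "cutoffs": [float(c) for c in self.cutoffs],
            "labels": list(self.labels),
            "exclusion_margin": float(self.exclusion_margin),
        }


def _edge_below(density: PopulationDensity, peak_idx: int, frac_height: float, side: int) -> float:
    """Nearest grid point on one side of a peak where density drops below
    ``frac_height`` x peak height; the grid end if it never does."""
    d, grid = density.density, density.grid
    target = frac_height * d[peak_idx]
    i = peak_idx
    while 0 <= i < d.size and d[i] >= target:
        i += side
    if i < 0:
        return float(grid[0])
    if i >= d.size:
        return float(grid[-1])
    return float(grid[i])


def derive_thresholds(
    density: PopulationDensity,
    peaks: Sequence[Peak],
    valleys: Sequence[float],
    category: str,
    prior_modal_ploidy: int | None = None,
    anchor_edge_fraction: float = 0.1,
    exclusion_divisor: float = 50.0,
) -> ThresholdSet:
    """Category-specific segmentation of a gene's population density.

    anchor: the highest peak is the modal (two-copy) state; its measured
    width — where density falls below ``anchor_edge_fraction`` of the peak
    height — bounds copy 2, and one peak-width further left bounds copy 1
    against copy 0.  high_freq_non_anchor: the three left-most peaks are
    0/1/2 copies with cutoffs at the valleys between them; beyond the
    third peak's right extent is 3+.  low_freq_non_anchor: the two
    left-most peaks are 0/1 copies; the 0/1 cutoff is the valley between
    them, and the inter-peak distance is added successively to place the
    1/2 and 2/3+ cutoffs.
    """
    gene = density.gene
    if category not in ("anchor", "high_freq_non_anchor", "low_freq_non_anchor"):
        raise ParameterError(f"cannot derive thresholds for category {category!r}")
    if not peaks:
        raise ThresholdError(f"{gene}: no peaks found")

    if category == "anchor":
        modal = prior_modal_ploidy if prior_modal_ploidy is not None else 2
        top = max(peaks, key=lambda p: p.height)
        left = _edge_below(density, top.grid_index, anchor_edge_fraction, -1)
        right = _edge_below(density, top.grid_index, anchor_edge_fraction, +1)
        width = right - left
        if width <= 0:
            raise ThresholdError(f"{gene}: anchor peak has zero width")
        cutoffs = [left - width, left, right]
        labels = [modal - 2, modal - 1, modal, modal + 1]
        # drop non-positive boundaries (no mass can sit left of zero)
        while cutoffs and cutoffs[0] <= 0:
            cutoffs.pop(0)
            labels.pop(0)
        margin_cutoff = left  # the 1-vs-2 boundary
    elif category == "high_freq_non_anchor":
        if len(peaks) < 3:
            raise ThresholdError(
                f"{gene}: {len(peaks)} peak(s) but category "
                f"high_freq_non_anchor expects >= 3; consider a manual "
                f"category override"
            )
        c01, c12 = valleys[0], valleys[1]
        if len(peaks) > 3:
            c23 = valleys[2]
        else:
            c23 = _edge_below(density, peaks[2].grid_index, anchor_edge_fraction, +1)
        cutoffs = [c01, c12, c23]
        labels = [0, 1, 2, 3]
        margin_cutoff = c12
    else:  # low_freq_non_anchor
        if len(peaks) < 2:
            raise ThresholdError(
                f"{gene}: {len(peaks)} peak(s) but category "
                f"low_freq_non_anchor expects >= 2; consider a manual "
                f"category override"
            )
        c01 = valleys[0]
        distance = peaks[1].location - peaks[0].location
        if distance <= 0:
            raise ThresholdError(f"{gene}: non-positive inter-peak distance")
        c12 = c01 + distance
        c23 = c01 + 2 * distance
        cutoffs = [c01, c12, c23]
        labels = [0, 1, 2, 3]
        margin_cutoff = c12

    margin = margin_cutoff / exclusion_divisor
    if margin <= 0:
        raise ThresholdError(f"{gene}: non-positive exclusion margin")
    return ThresholdSet(
        gene=gene,
        cutoffs=np.asarray(cutoffs, dtype=float),
        labels=[min(max(l, 0), THREE_PLUS) for l in labels],
        exclusion_margin=margin,
    )


def assign_copy_number(frequency: float, thresholds: ThresholdSet) -> int | None:
    """Copy number of one sample for one gene; ``None`` means excluded
    (within the exclusion margin of a boundary)."""
    if frequency < 0:
        raise ParameterError("frequency must be non-negative")
    if np.any(np.abs(thresholds.cutoffs - frequency) < thresholds.exclusion_margin):
        return None
    idx = int(np.searchsorted(thresholds.cutoffs, frequency, side="right"))
    return thresholds.labels[idx]


# ---------------------------------------------------------------------------
# Copy-number matrix and co-segregation
# ---------------------------------------------------------------------------


class CopyNumberMatrix:
    """Samples x genes integer copy calls (3 encodes "3+").

    ``calls`` is a nullable-integer DataFrame where ``pd.NA`` marks an
    excluded cell; ``flags`` records per-cell provenance (measured,
    inferred, inferred_clamped, excluded).
    """

    def __init__(self, calls: pd.DataFrame, flags: pd.DataFrame | None = None):
        self.calls = calls.astype("Int64")
        if flags is None:
            flags = pd.DataFrame(
                np.where(self.calls.isna(), EXCLUDED, MEASURED),
                index=self.calls.index,
                columns=self.calls.columns,
            )
        self.flags = flags

    @property
    def samples(self) -> pd.Index:
        return self.calls.index

    @property
    def genes(self) -> pd.Index:
        return self.calls.columns

    def fraction_excluded(self, genes: Iterable[str] | None = None) -> float:
        sub = self.calls if genes is None else self.calls[list(genes)]
        return float(sub.isna().to_numpy().mean())

    def copy(self) -> "CopyNumberMatrix":
        return CopyNumberMatrix(self.calls.copy(), self.flags.copy())

    def write_tsv(self, path: str | Path, flags_path: str | Path | None = None) -> None:
        display = self.calls.astype(object).copy()
        display[self.calls == THREE_PLUS] = "3+"
        display[self.calls.isna()] = "NA"
        display.to_csv(path, sep="\t", index_label="sample")
        if flags_path is not None:
            self.flags.to_csv(flags_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path: str | Path, flags_path: str | Path | None = None) -> "CopyNumberMatrix":
        raw = pd.read_csv(path, sep="\t", index_col="sample", dtype=str)
        calls = raw.replace({"3+": "3", "NA": None}).astype("float").astype("Int64")
        flags = None
        if flags_path is not None:
            flags = pd.read_csv(flags_path, sep="\t", index_col="sample", dtype=str)
        return cls(calls, flags)


def infer_cosegregating(
    matrix: CopyNumberMatrix, rules: Sequence[CosegRule]
) -> CopyNumberMatrix:
    """Extend a measured matrix with rule-derived genes.

    For each rule target, a sample's call is derived from its source-gene
    calls; if any source is excluded for that sample the target is
    excluded too.  Sums are capped at 3 ("3+"); inverse rules clamp below
    at 0 with an ``inferred_clamped`` flag.
    """
    out = matrix.copy()
    for rule in rules:
        missing = [g for g in rule.sources if g not in out.calls.columns]
        if missing:
            raise ConfigError(
                f"rule for {rule.target} references unknown gene(s): {missing}"
            )
        if rule.target in matrix.calls.columns:
            raise ConfigError(
                f"rule target {rule.target} is already a measured gene"
            )
        source = out.calls[list(rule.sources)]
        total = source.sum(axis=1, skipna=False)
        if rule.mode == "sum":
            values = total.clip(upper=THREE_PLUS)
            clamped = np.zeros(len(values), dtype=bool)
        else:
            raw = rule.baseline - total
            clamped = (raw < 0).fillna(False).to_numpy(dtype=bool)
            values = raw.clip(lower=0, upper=THREE_PLUS)
        excluded = total.isna().to_numpy(dtype=bool)
        values[excluded] = pd.NA
        out.calls[rule.target] = values.astype("Int64")
        flag = np.where(
            excluded, EXCLUDED, np.where(clamped, INFERRED_CLAMPED, INFERRED)
        )
        out.flags[rule.target] = flag
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class KirCopyNumberModel:
    """Cohort-level copy-number model over a gene-frequency matrix.

    Parameters
    ----------
    frequencies
        Samples x genes DataFrame of normalized mean unique-k-mer
        frequencies (only genes with unique k-mers appear as columns).
    config
        Gene categories, modal-ploidy priors and co-segregation rules.
    min_cohort
        Minimum cohort size; the density modes are not identifiable on
        small cohorts.
    grid_points, min_prominence, anchor_edge_fraction, exclusion_divisor,
    bandwidth
        Density and thresholding tuning knobs (see the corresponding
        free functions).
    """

    def __init__(
        self,
        frequencies: pd.DataFrame,
        config: GeneCategoryConfig,
        *,
        min_cohort: int = 50,
        grid_points: int = 512,
        min_prominence: float = 0.02,
        anchor_edge_fraction: float = 0.1,
        exclusion_divisor: float = 50.0,
        bandwidth: float | None = None,
    ):
        self.frequencies = frequencies
        self.config = config
        self.min_cohort = min_cohort
        self.grid_points = grid_points
        self.min_prominence = min_prominence
        self.anchor_edge_fraction = anchor_edge_fraction
        self.exclusion_divisor = exclusion_divisor
        self.bandwidth = bandwidth
        unknown = [
            g
            for g in frequencies.columns
            if g not in config.category
        ]
        if unknown:
            raise ConfigError(f"genes without a category: {unknown}")

    @property
    def measured_genes(self) -> list[str]:
        return [
            g
            for g in self.frequencies.columns
            if self.config.category[g] != "inferred"
        ]

    def fit(self) -> "KirCopyNumberResults":
        """Estimate densities, derive thresholds and call every sample."""
        if len(self.frequencies) < self.min_cohort:
            raise DensityError(
                f"cohort of {len(self.frequencies)} samples is below the "
                f"model floor of {self.min_cohort}"
            )
        densities: dict[str, PopulationDensity] = {}
        peaks: dict[str, list[Peak]] = {}
        valleys: dict[str, list[float]] = {}
        thresholds: dict[str, ThresholdSet] = {}
        calls = pd.DataFrame(
            index=self.frequencies.index, columns=self.measured_genes, dtype=object
        )
        for gene in self.measured_genes:
            category = self.config.category[gene]
            values = self.frequencies[gene].to_numpy(dtype=float)
            dens = estimate_density(
                values,
                gene=gene,
                bandwidth=self.bandwidth,
                grid_points=self.grid_points,
                min_samples=self.min_cohort,
            )
            pk, vl = find_peaks_valleys(dens, self.min_prominence)
            ts = derive_thresholds(
                dens,
                pk,
                vl,
                category,
                prior_modal_ploidy=self.config.modal_ploidy(gene),
                anchor_edge_fraction=self.anchor_edge_fraction,
                exclusion_divisor=self.exclusion_divisor,
            )
            densities[gene], peaks[gene], valleys[gene] = dens, pk, vl
            thresholds[gene] = ts
            calls[gene] = [assign_copy_number(v, ts) for v in values]
        matrix = CopyNumberMatrix(calls)
        applicable = [
            r
            for r in self.config.coseg_rules
            if r.target in self.config.category
            and all(s in matrix.calls.columns for s in r.sources)
        ]
        skipped = [
            r.target
            for r in self.config.coseg_rules
            if r not in applicable and r.target in self.config.category
        ]
        if skipped:
            warnings.warn(
                f"co-segregation rules skipped (sources not measured): {skipped}",
                KircallWarning,
                stacklevel=2,
            )
        matrix = infer_cosegregating(matrix, applicable)
        return KirCopyNumberResults(
            model=self,
            densities=densities,
            peaks=peaks,
            valleys=valleys,
            thresholds=thresholds,
            copy_numbers=matrix,
        )


@dataclass
class KirCopyNumberResults:
    """Fitted thresholds, per-cell calls and diagnostics."""

    model: KirCopyNumberModel
    densities: dict[str, PopulationDensity]
    peaks: dict[str, list[Peak]]
    valleys: dict[str, list[float]]
    thresholds: dict[str, ThresholdSet]
    copy_numbers: CopyNumberMatrix

    def summary(self) -> pd.DataFrame:
        """Per-gene fit summary: category, peak count, cutoffs, margin,
        copy-state counts and excluded fraction."""
        rows = []
        calls = self.copy_numbers.calls
        for gene in calls.columns:
            cat = self.model.config.category.get(gene, "?")
            ts = self.thresholds.get(gene)
            col = calls[gene]
            counts = col.value_counts(dropna=True)
            rows.append(
                {
                    "gene": gene,
                    "category": cat,
                    "n_peaks": len(self.peaks.get(gene, [])) or pd.NA,
                    "cutoffs": (
                        ", ".join(f"{c:.3f}" for c in ts.cutoffs) if ts else ""
                    ),
                    "exclusion_margin": ts.exclusion_margin if ts else pd.NA,
                    "n0": int(counts.get(0, 0)),
                    "n1": int(counts.get(1, 0)),
                    "n2": int(counts.get(2, 0)),
                    "n3plus": int(counts.get(3, 0)),
                    "excluded_frac": float(col.isna().mean()),
                }
            )
        return pd.DataFrame(rows).set_index("gene")

    def gene_frequencies(self) -> pd.Series:
        from .population import gene_frequencies

        return gene_frequencies(self.copy_numbers)

    def thresholds_to_json(self, path: str | Path) -> None:
        import json

        payload = {g: ts.to_dict() for g, ts in self.thresholds.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def plot_density(self, gene: str, ax=None):
        """Density curve with peaks and copy-number cutoffs for one gene."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dens = self.densities[gene]
        ax.plot(dens.grid, dens.density, color="steelblue")
        for p in self.peaks[gene]:
            ax.axvline(p.location, color="grey", ls=":", lw=0.8)
        for c in self.thresholds[gene].cutoffs:
            ax.axvline(c, color="green", ls="--", lw=1.0)
        ax.set_xlabel("normalized k-mer frequency")
        ax.set_ylabel("density")
        ax.set_title(gene)
        return ax
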