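"""Inhibitory-KIR burden and survival comparison.

The *inhibitory burden* of a sample is the summed copy number of the
inhibitory KIR genes ("3+" counted as 3).  Cohorts are split at the
median burden — low means at-or-below the median — and survival between
the two groups is compared with Kaplan-Meier curves and the log-rank
test (delegated to lifelines), with Bonferroni adjustment across tumor
types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, KircallWarning, ParameterError
from .model import CopyNumberMatrix

#: Canonical inhibitory KIR genes; configuration data to be reviewed per
#: study (long-tailed 2DL/3DL receptors carry ITIM inhibitory motifs).
DEFAULT_INHIBITORY_GENES: tuple[str, ...] = (
    "KIR2DL1",
    "KIR2DL2",
    "KIR2DL3",
    "KIR2DL5",
    "KIR3DL1",
    "KIR3DL2",
    "KIR3DL3",
)


def inhibitory_burden(
    matrix: CopyNumberMatrix, inhibitory_genes: Sequence[str]
) -> pd.Series:
    """Per-sample summed inhibitory copy number.

    Samples with an excluded call at any inhibitory gene are dropped with
    a warning rather than partially summed.
    """
    if not inhibitory_genes:
        raise ConfigError("inhibitory gene list is empty")
    missing = [g for g in inhibitory_genes if g not in matrix.calls.columns]
    if missing:
        raise ConfigError(f"inhibitory genes not in matrix: {missing}")
    sub = matrix.calls[list(inhibitory_genes)]
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} sample(s) dropped: excluded inhibitory-gene calls",
            KircallWarning,
            stacklevel=2,
        )
    burden = sub[complete].sum(axis=1).astype(int)
    burden.name = "inhibitory_copies"
    return burden


def split_by_median(burdens: pd.Series) -> pd.DataFrame:
    """Partition samples into low (<= median) and high (> median) burden."""
    if len(burdens) < 2:
        raise ParameterError("need >= 2 samples to split")
    med = float(burdens.median())
    group = np.where(burdens <= med, "low", "high")
    if (group == "high").sum() == 0:
        raise ParameterError(
            "degenerate split: no sample exceeds the median burden"
        )
    return pd.DataFrame(
        {"inhibitory_copies": burdens, "group": group}, index=burdens.index
    )


@dataclass
class SurvivalComparison:
    """Log-rank comparison of low- versus high-burden survival."""

    p_value: float
    p_adjusted: float
    test_statistic: float
    n_low: int
    n_high: int
    km_fits: dict  # group -> fitted lifelines KaplanMeierFitter

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for group, km in self.km_fits.items():
            km.plot_survival_function(ax=ax, label=f"{group} burden")
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        return ax


def compare_survival(
    groups: pd.DataFrame,
    times: pd.Series | Mapping[str, float],
    events: pd.Series | Mapping[str, int],
    n_tests: int = 1,
) -> SurvivalComparison:
    """Kaplan-Meier + log-rank comparison between burden groups.

    ``groups`` is the output of :func:`split_by_median`; ``times`` are
    non-negative durations and ``events`` binary indicators, indexed by
    sample.  The adjusted p-value is the Bonferroni ``min(1, p * n_tests)``.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = pd.Series(times)
    events = pd.Series(events)
    shared = groups.index.intersection(times.index).intersection(events.index)
    if shared.empty:
        raise ParameterError("no samples shared between groups and clinical data")
    g = groups.loc[shared, "group"]
    t = times.loc[shared].astype(float)
    e = events.loc[shared].astype(int)
    if (t < 0).any():
        raise ParameterError("survival times must be non-negative")
    if not set(e.unique()) <= {0, 1}:
        raise ParameterError("event indicators must be binary")
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    low, high = g == "low", g == "high"
    if low.sum() == 0 or high.sum() == 0:
        raise ParameterError("both burden groups must be non-empty")

    result = logrank_test(t[low], t[high], event_observed_A=e[low], event_observed_B=e[high])
    km_fits = {}
    for name, mask in (("low", low), ("high", high)):
        km = KaplanMeierFitter()
        km.fit(t[mask], event_observed=e[mask], label=name)
        km_fits[name] = km
    p = float(result.p_value)
    return SurvivalComparison(
        p_value=p,
        p_adjusted=min(1.0, p * n_tests),
        test_statistic=float(result.test_statistic),
        n_low=int(low.sum()),
        n_high=int(high.sum()),
        km_fits=km_fits,
    )
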