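"""Population gene frequencies and concordance with reference populations.

The *gene frequency* is the average gene copy number per haplotype: the
mean copy number over non-excluded samples divided by two.  Comparing
called frequencies against an independently typed reference population is
the standard cohort-level sanity check for the caller.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from scipy import stats

from .exceptions import KircallWarning, ParameterError
from .model import CopyNumberMatrix


def gene_frequencies(matrix: CopyNumberMatrix) -> pd.Series:
    """Per-gene average copy number per haplotype.

    Excluded cells are dropped per gene (not imputed); "3+" calls count as
    exactly 3.  A gene whose cells are all excluded is omitted with a
    warning.
    """
    out = {}
    for gene in matrix.genes:
        col = matrix.calls[gene].dropna()
        if col.empty:
            warnings.warn(
                f"gene {gene} has no non-excluded calls; omitted",
                KircallWarning,
                stacklevel=2,
            )
            continue
        out[gene] = float(col.mean()) / 2.0
    return pd.Series(out, name="frequency")


def correlate_frequencies(
    predicted: pd.Series, reference: pd.Series
) -> tuple[float, float]:
    """Pearson correlation (r, r^2) over the genes shared by both tables."""
    shared = predicted.index.intersection(reference.index)
    if len(shared) < 3:
        raise ParameterError(
            f"only {len(shared)} genes shared between tables; need >= 3"
        )
    x = predicted.loc[shared].astype(float)
    y = reference.loc[shared].astype(float)
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ParameterError("zero variance in a frequency table")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def load_frequency_table(path: str | Path) -> pd.Series:
    """Read a TSV of (gene, frequency) into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParameterError("frequency table needs columns gene, frequency")
    return pd.Series(
        df.iloc[:, 1].astype(float).to_numpy(),
        index=df.iloc[:, 0].astype(str),
        name="frequency",
    )


def write_frequency_table(freqs: pd.Series, path: str | Path) -> None:
    freqs.rename("frequency").rename_axis("gene").to_csv(path, sep="\t")
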