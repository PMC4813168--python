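"""Expression preprocessing and differential-expression summaries.

The pipeline accepts gene-level (or probe-level) expression matrices that are
already background-adjusted. Two classic microarray preprocessing steps are
provided — quantile normalization and Tukey median-polish summarization — plus
a per-gene two-sample differential-expression statistic with Bonferroni
control, used to report the fraction of differentially expressed genes between
two disease stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Gene-level expression for one stage: genes x samples.

    ``values`` is a DataFrame indexed by gene id with one column per sample.
    ``stage`` is a free label; the study design uses C (control), I (<=3 h),
    II (5 h) and III (24 h post-stroke).
    """

    values: pd.DataFrame
    stage: str = "C"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ValueError("non-finite values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(float)


@dataclass
class ProbeMatrix:
    """Probe-level expression plus a probe -> gene map (each probe maps to at
    most one gene)."""

    values: pd.DataFrame
    probe_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        unknown = set(self.probe_to_gene) - set(self.values.index)
        if unknown:
            raise ValueError(f"probe map refers to unknown probes: {sorted(unknown)[:5]}")


def quantile_normalize(matrix):
    """Force every column to share the same value distribution.

    Each column is replaced by the cross-column mean of the order statistics,
    mapped back through the column's own ranks; within-column rank order is
    preserved. Tied values receive the mean of the reference values across
    their tied ranks (average-rank dialect).

    Accepts and returns either a DataFrame or a 2-D array.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(float) if is_frame else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("expected a 2-D matrix with at least one column")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")  # 1-based, may be *.5
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def median_polish(X: np.ndarray, max_iter: int = 10, tol: float = 1e-6):
    """Tukey median polish of a 2-D table.

    Fits the additive model ``x[r, c] = overall + row[r] + col[c] + resid`` by
    alternately sweeping out row and column medians, at most ``max_iter``
    iterations or until the total absolute residual changes by less than
    ``tol``. Returns ``(overall, row_effects, col_effects, residuals)``.
    """
    R = np.array(X, dtype=float)
    if R.ndim != 2 or R.size == 0:
        raise ValueError("expected a non-empty 2-D table")
    n_rows, n_cols = R.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    last = np.abs(R).sum()
    for _ in range(max_iter):
        rm = np.median(R, axis=1)
        R -= rm[:, None]
        row_eff += rm
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta
        cm = np.median(R, axis=0)
        R -= cm[None, :]
        col_eff += cm
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta
        total = np.abs(R).sum()
        if abs(last - total) < tol * max(total, 1.0):
            break
        last = total
    return overall, row_eff, col_eff, R


def median_polish_summarize(probes: ProbeMatrix, stage: str = "C") -> ExpressionMatrix:
    """Summarize probe-level values to one expression row per gene.

    For each gene, Tukey median polish is run on its probe x sample submatrix
    and the gene's per-sample expression is ``overall + sample_effect`` (probe
    effects are discarded), i.e. RMA-style summarization.
    """
    if not probes.probe_to_gene:
        raise ValueError("empty probe -> gene map")
    by_gene: dict[str, list[str]] = {}
    for probe, gene in probes.probe_to_gene.items():
        by_gene.setdefault(gene, []).append(probe)
    rows = {}
    for gene in sorted(by_gene):
        members = sorted(by_gene[gene])
        if not members:
            raise ValueError(f"gene {gene} has no probes")
        sub = probes.values.loc[members].to_numpy(float)
        overall, _, col_eff, _ = median_polish(sub)
        rows[gene] = overall + col_eff
    values = pd.DataFrame.from_dict(rows, orient="index", columns=probes.values.columns)
    return ExpressionMatrix(values=values.sort_index(), stage=stage)


def deg_fraction(a: ExpressionMatrix, b: ExpressionMatrix, alpha: float = 0.05):
    """Fraction of genes differentially expressed between two stages.

    Per shared gene, a Welch two-sample t-test is applied across samples; the
    p-values are Bonferroni-corrected by the number of tested genes and the
    fraction of genes with corrected p <= ``alpha`` is returned along with the
    per-gene corrected p-values.
    """
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValueError("the two matrices share no genes")
    if a.n_samples < 2 or b.n_samples < 2:
        raise ValueError("each stage needs at least 2 samples")
    xa = a.values.loc[shared].to_numpy(float)
    xb = b.values.loc[shared].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance genes yield NaN p
        _, pvals = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    corrected = np.clip(pvals * len(shared), 0.0, 1.0)
    fraction = float(np.mean(corrected <= alpha))
    return fraction, pd.Series(corrected, index=shared, name="p_bonferroni")
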