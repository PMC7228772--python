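"""Tissue-restriction of hit genes: specificity ratios and a resampling test.

Autoimmune-syndrome antigens are expected to be tissue-restricted. For each
gene we compute a specificity ratio

    ratio = max over tissues / sum over tissues

of its consensus expression profile (1 = expressed in a single tissue,
1/n_tissues = perfectly broad). Whether a hit set is more restricted than
chance is assessed by iterative resampling: gene sets of the same size are
drawn uniformly from all testable genes, and the observed mean ratio is
compared with the null distribution of resampled mean ratios. The empirical
p-value uses the add-one estimator, so it is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpecificityResult",
    "specificity_ratio",
    "specificity_ratios",
    "resampling_enrichment_test",
    "read_expression_wide",
    "read_expression_hpa",
]


class InsufficientDataError(ValueError):
    """Too few mappable hit genes to run the resampling test."""


def specificity_ratio(row: np.ndarray | pd.Series) -> float:
    """max/sum expression ratio of one gene across tissues; in (0, 1]."""
    values = np.asarray(row, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("expression row must be a non-empty 1-D vector")
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    total = values.sum()
    if total == 0:
        raise ValueError("all-zero expression row has no defined specificity ratio")
    return float(values.max() / total)


def specificity_ratios(expr: pd.DataFrame) -> pd.Series:
    """Per-gene max/sum ratios; all-zero rows are dropped with a warning."""
    totals = expr.sum(axis=1)
    dead = expr.index[totals == 0]
    if len(dead) > 0:
        warnings.warn(
            f"dropping {len(dead)} genes with all-zero expression: "
            f"{list(dead[:5])}", stacklevel=2,
        )
    live = expr.loc[totals > 0]
    return live.max(axis=1) / live.sum(axis=1)


@dataclass
class SpecificityResult:
    """Outcome of the resampling tissue-restriction test."""

    observed_mean_ratio: float
    null_means: np.ndarray
    fold_vs_null: float
    empirical_p: float
    n_iter: int
    n_genes: int
    seed: int | None
    missing_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "observed_mean_ratio": self.observed_mean_ratio,
            "fold_vs_null": self.fold_vs_null,
            "empirical_p": self.empirical_p,
            "n_iter": self.n_iter,
            "n_genes": self.n_genes,
            "seed": self.seed,
            "missing_genes": list(self.missing_genes),
        }


def resampling_enrichment_test(
    hit_genes: set[str] | list[str],
    expr: pd.DataFrame,
    n_iter: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> SpecificityResult:
    """One-sided resampling test for tissue restriction of a hit-gene set.

    The observed statistic is the mean specificity ratio of the hit genes
    present in ``expr`` (genes absent from the matrix are reported in the
    result, not silently dropped). Each of ``n_iter`` iterations draws the
    same number of genes uniformly without replacement from all genes with
    nonzero total expression (hits included) and records the mean ratio.

    empirical_p = (1 + #{null mean >= observed}) / (n_iter + 1), one-sided
    for restriction: higher ratio = more tissue-restricted.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100 for a meaningful null")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratios = specificity_ratios(expr)
    hit_genes = sorted(set(hit_genes))
    present = [g for g in hit_genes if g in ratios.index]
    missing = [g for g in hit_genes if g not in ratios.index]
    if len(present) < 2:
        raise InsufficientDataError(
            f"only {len(present)} hit genes present in the expression matrix; need >= 2"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float(ratios.loc[present].mean())

    pool = ratios.to_numpy()
    k = len(present)
    null_means = np.empty(n_iter)
    for i in range(n_iter):
        null_means[i] = pool[rng.choice(pool.size, size=k, replace=False)].mean()

    exceed = int(np.sum(null_means >= observed))
    empirical_p = (1 + exceed) / (n_iter + 1)
    fold = observed / float(null_means.mean())
    return SpecificityResult(
        observed_mean_ratio=observed,
        null_means=null_means,
        fold_vs_null=fold,
        empirical_p=empirical_p,
        n_iter=n_iter,
        n_genes=k,
        seed=seed if isinstance(seed, int) else None,
        missing_genes=missing,
    )


def read_expression_wide(path) -> pd.DataFrame:
    """Read a wide gene x tissue expression TSV (first column = gene)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 tissue columns")
    return expr


def read_expression_hpa(path) -> pd.DataFrame:
    """Read a long-format consensus expression TSV (columns Gene, Tissue, nTPM).

    This is the layout of the Human Protein Atlas consensus download
    (``rna_tissue_consensus.tsv``); a ``Gene name`` column is preferred over
    the Ensembl ``Gene`` column when both are present.
    """
    long = pd.read_csv(path, sep="\t")
    gene_col = "Gene name" if "Gene name" in long.columns else "Gene"
    value_col = next((c for c in ("nTPM", "NX", "TPM") if c in long.columns), None)
    if gene_col not in long.columns or "Tissue" not in long.columns or value_col is None:
        raise ValueError("expected long-format columns Gene[ name], Tissue, nTPM")
    wide = long.pivot_table(index=gene_col, columns="Tissue", values=value_col,
                            aggfunc="max")
    return wide.fillna(0.0)
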