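"""Hit calling: from gene enrichments to candidate autoantigen lists.

A gene is "positive" in a sample when its fold-change over the mock-IP mean
is 10-fold or greater (inclusive boundary). Candidate antigens are genes
positive in at least ``min_cases`` case sera and at most ``max_controls``
control sera (default zero — one control positive disqualifies a gene).
Mock samples never count toward either tally, and validation-cohort samples
are excluded from discovery criteria by default.

Also here: partitioning candidates into literature-known vs novel, ranking
genes by how many case sera share them, and z-scoring + hierarchical
clustering (1 - Pearson correlation, average linkage) of enrichment rows for
heatmap rendering. All orderings are deterministic; ties break alphabetically
by gene symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CandidateSet",
    "call_positive_genes",
    "candidate_antigens",
    "cross_reference_known",
    "rank_by_frequency",
    "zscore_and_cluster",
    "load_known_antigens",
]


def call_positive_genes(fold: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Boolean gene x sample positivity: fold-change >= threshold.

    The boundary is inclusive: a gene at exactly the threshold is positive.
    """
    if threshold <= 0:
        raise ValueError("positivity threshold must be > 0")
    pos = fold >= threshold
    pos.attrs["threshold_fold"] = threshold
    return pos


@dataclass
class CandidateSet:
    """Genes meeting the case/control criteria, with their per-role tallies.

    ``table`` columns: gene, n_case_pos, n_control_pos; rows sorted by
    descending case count then alphabetically.
    """

    table: pd.DataFrame
    min_cases: int
    max_controls: int

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.table["gene"])


def _role_ids(pos: pd.DataFrame, roles: pd.Series, role: str,
              cohort: pd.Series | None, discovery_only: bool) -> list[str]:
    roles = roles.reindex(pos.columns)
    if roles.isna().any():
        missing = list(pos.columns[roles.isna()])
        raise ValueError(f"samples without role assignment: {missing}")
    keep = roles == role
    if discovery_only and cohort is not None:
        keep &= cohort.reindex(pos.columns) != "validation"
    return list(pos.columns[keep])


def candidate_antigens(
    pos: pd.DataFrame,
    roles: pd.Series,
    min_cases: int,
    max_controls: int = 0,
    cohort: pd.Series | None = None,
    discovery_only: bool = True,
) -> CandidateSet:
    """Candidate antigens: >= min_cases case positives, <= max_controls control positives.

    Mock samples are ignored; validation-cohort samples are excluded when
    ``discovery_only`` (the default) and a cohort labelling is supplied.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    if max_controls < 0:
        raise ValueError("max_controls must be >= 0")
    case_ids = _role_ids(pos, roles, "case", cohort, discovery_only)
    control_ids = _role_ids(pos, roles, "control", cohort, discovery_only)
    n_case = pos[case_ids].sum(axis=1).astype(int)
    n_control = pos[control_ids].sum(axis=1).astype(int)
    keep = (n_case >= min_cases) & (n_control <= max_controls)
    table = pd.DataFrame(
        {"gene": pos.index[keep], "n_case_pos": n_case[keep].to_numpy(),
         "n_control_pos": n_control[keep].to_numpy()}
    )
    table = table.sort_values(
        ["n_case_pos", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return CandidateSet(table=table, min_cases=min_cases, max_controls=max_controls)


def cross_reference_known(
    candidates: CandidateSet, known_genes: set[str]
) -> tuple[list[str], list[str]]:
    """Partition candidates into (known, novel) by the curated literature list.

    Both lists preserve the candidate ordering; together they partition the
    candidate set.
    """
    known = [g for g in candidates.genes if g in known_genes]
    novel = [g for g in candidates.genes if g not in known_genes]
    return known, novel


def rank_by_frequency(pos: pd.DataFrame, roles: pd.Series,
                      cohort: pd.Series | None = None,
                      discovery_only: bool = True) -> pd.DataFrame:
    """All genes ranked by the number of positive case sera (desc, ties alphabetical)."""
    case_ids = _role_ids(pos, roles, "case", cohort, discovery_only)
    if len(case_ids) == 0:
        raise ValueError("no case samples available for ranking")
    table = pd.DataFrame({
        "gene": pos.index,
        "n_positive_cases": pos[case_ids].sum(axis=1).astype(int).to_numpy(),
    })
    return table.sort_values(
        ["n_positive_cases", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def zscore_and_cluster(
    fold: pd.DataFrame,
    genes: list[str] | None = None,
    method: str = "average",
) -> tuple[pd.DataFrame, list[str], list[str], list[str]]:
    """Z-score gene rows and hierarchically cluster rows and columns.

    Each row is centred and scaled by its sample (n-1) standard deviation.
    Distance is 1 - Pearson correlation; linkage is average by default
    (``method='complete'`` available). Zero-variance rows cannot be
    correlated: they get all-zero z-scores, are flagged, and are placed last
    (alphabetically) in the row order.

    Returns (z_matrix, row_order, col_order, flagged_rows).
    """
    sub = fold.loc[list(genes)] if genes is not None else fold
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("clustering needs at least 2 genes and 2 samples")
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    flagged = sorted(sub.index[(sd == 0) | ~np.isfinite(sd)])
    z = sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    z.loc[flagged] = 0.0

    ok = [g for g in sub.index if g not in set(flagged)]
    if len(ok) >= 2:
        zok = z.loc[ok]
        row_order = [ok[i] for i in _corr_leaf_order(zok.to_numpy(), method)]
    else:
        row_order = list(ok)
    row_order += flagged

    if len(ok) >= 2:
        col_mat = z.loc[ok].to_numpy().T
        col_order = [sub.columns[i] for i in _corr_leaf_order(col_mat, method)]
    else:
        col_order = list(sub.columns)
    return z, row_order, list(col_order), flagged


def _corr_leaf_order(mat: np.ndarray, method: str) -> np.ndarray:
    """Leaf order from average/complete linkage on 1 - Pearson row distances."""
    if mat.shape[0] == 1:
        return np.array([0])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    dist = 1.0 - corr
    # rows/cols that are constant have undefined correlation: maximal distance
    dist = np.where(np.isfinite(dist), dist, 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method=method)
    return leaves_list(Z)


def load_known_antigens() -> set[str]:
    """Curated literature-reported APS1 autoantigen gene symbols shipped with the package."""
    text = (resources.files("phipdiscover") / "data" / "known_antigens.txt").read_text()
    return {line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")}
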