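"""Autoantibody–phenotype association by two-sample Kolmogorov–Smirnov tests.

For each (gene, clinical phenotype) pair, the per-sample gene enrichments of
cases WITH the phenotype are compared to those WITHOUT it using a two-sided
two-sample KS test. Because the KS statistic depends only on ranks, the test
is invariant to any strictly increasing transform of the enrichments (fold
vs log-fold is immaterial).

Associations whose enrichment is higher in unaffected individuals are
clinically "protective-direction" signals; following the screen's design
they are masked (p set to 1) when significant, so only disease-elevated
associations survive. Benjamini–Hochberg adjustment is available but off by
default (the screen reports raw p-values).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ks_association",
    "directional_mask",
    "association_screen",
    "read_phenotype_table",
]

#: below this product of group sizes the exact KS distribution is used
EXACT_KS_MAX = 10_000

ASSOC_COLUMNS = ["gene", "phenotype", "D", "p_raw", "p_masked", "direction",
                 "n_with", "n_without", "masked_flag"]


def ks_association(
    values: pd.Series,
    phenotype: pd.Series,
    min_group_size: int = 3,
) -> dict:
    """Two-sided two-sample KS test of enrichments with vs without a phenotype.

    ``values`` are one gene's enrichments per case sample; ``phenotype`` is a
    binary indicator over (a superset of) the same samples, NaN = unknown
    (dropped pairwise). Returns a dict with keys D, p, direction (mean(with)
    - mean(without)), n_with, n_without; when either group is smaller than
    ``min_group_size`` the result is marked missing (NaN statistics) rather
    than raising.
    """
    common = values.index.intersection(phenotype.index)
    vals = values.loc[common].astype(float)
    phen = phenotype.loc[common].astype(float)
    keep = phen.notna() & vals.notna()
    vals, phen = vals[keep], phen[keep]
    with_v = vals[phen == 1].to_numpy()
    without_v = vals[phen == 0].to_numpy()
    n1, n0 = len(with_v), len(without_v)
    if n1 < min_group_size or n0 < min_group_size:
        return {"D": np.nan, "p": np.nan, "direction": np.nan,
                "n_with": n1, "n_without": n0}
    method = "exact" if n1 * n0 <= EXACT_KS_MAX else "asymp"
    res = stats.ks_2samp(with_v, without_v, alternative="two-sided", method=method)
    return {
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "direction": float(with_v.mean() - without_v.mean()),
        "n_with": n1,
        "n_without": n0,
    }


def directional_mask(assoc: pd.DataFrame, alpha_mask: float = 0.05) -> pd.DataFrame:
    """Mask significant protective-direction associations.

    Entries with direction <= 0 (enrichment higher WITHOUT the phenotype)
    and raw p < ``alpha_mask`` get p_masked = 1 and masked_flag = True; all
    other entries keep p_masked = p_raw. Missing entries stay missing.
    """
    out = assoc.copy()
    mask = (out["direction"] <= 0) & (out["p_raw"] < alpha_mask)
    mask = mask.fillna(False)
    out["p_masked"] = out["p_raw"].where(~mask, 1.0)
    out["masked_flag"] = mask.to_numpy()
    return out


def association_screen(
    enr: pd.DataFrame,
    phen: pd.DataFrame,
    genes: list[str] | None = None,
    phenotypes: list[str] | None = None,
    min_group_size: int = 3,
    alpha_mask: float = 0.05,
    bh_adjust: bool = False,
    sex: pd.Series | None = None,
    sex_specific: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full gene x phenotype KS association screen, long format.

    ``enr`` is a gene x case-sample enrichment matrix; ``phen`` a case-sample
    x phenotype binary table (NaN allowed). Phenotypes flagged in
    ``sex_specific`` (phenotype -> 'F'/'M') restrict the tested population to
    that sex when a ``sex`` series is supplied. Output columns: gene,
    phenotype, D, p_raw, p_masked, direction, n_with, n_without, masked_flag
    (plus p_bh when ``bh_adjust``). Row order is deterministic: genes then
    phenotypes, each in the requested (or natural) order.
    """
    if phen.shape[1] == 0 or phen.shape[0] == 0:
        raise ValueError("phenotype table is empty")
    genes = list(genes) if genes is not None else list(enr.index)
    unknown = [g for g in genes if g not in enr.index]
    if unknown:
        raise KeyError(f"genes absent from enrichment matrix: {unknown[:5]}")
    phenotypes = list(phenotypes) if phenotypes is not None else list(phen.columns)
    sex_specific = sex_specific or {}

    rows = []
    for gene in genes:
        values = enr.loc[gene]
        for name in phenotypes:
            col = phen[name]
            if name in sex_specific and sex is not None:
                keep = sex.reindex(col.index) == sex_specific[name]
                col = col[keep.fillna(False)]
            res = ks_association(values, col, min_group_size=min_group_size)
            rows.append((gene, name, res["D"], res["p"], res["direction"],
                         res["n_with"], res["n_without"]))
    out = pd.DataFrame(rows, columns=["gene", "phenotype", "D", "p_raw",
                                      "direction", "n_with", "n_without"])
    out = directional_mask(out, alpha_mask=alpha_mask)
    if bh_adjust:
        ok = out["p_raw"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = stats.false_discovery_control(
                out.loc[ok, "p_raw"].to_numpy(), method="bh")
        out["p_bh"] = adj
    return out[ASSOC_COLUMNS + (["p_bh"] if bh_adjust else [])]


def to_wide(assoc: pd.DataFrame, value: str = "p_masked") -> pd.DataFrame:
    """Pivot the long association table into a gene x phenotype matrix."""
    return assoc.pivot(index="gene", columns="phenotype", values=value)


def read_phenotype_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read the binary phenotype CSV (rows = case samples, columns = phenotypes).

    A leading comment line of the form ``# sex_specific: POI=F; EH=M`` marks
    phenotypes tested only in one sex. Returns (table, sex_specific_map).
    Cells may be 0, 1, or empty (missing).
    """
    sex_specific: dict[str, str] = {}
    with open(path) as fh:
        first = fh.tell()
        line = fh.readline()
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("sex_specific:"):
                spec = body.split(":", 1)[1]
                for item in spec.split(";"):
                    item = item.strip()
                    if item:
                        name, sx = item.split("=")
                        sex_specific[name.strip()] = sx.strip()
        else:
            fh.seek(first)
        table = pd.read_csv(fh, index_col=0)
    bad = set(table.stack().dropna().unique()) - {0, 1, 0.0, 1.0}
    if bad:
        raise ValueError(f"phenotype table must be binary/NA; found {sorted(bad)}")
    return table, sex_specific
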