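"""Radioligand binding assay (RLBA) statistics.

The orthogonal validation assay immunoprecipitates in-vitro-translated,
35S-labelled full-length protein with serum; the readout is counts per
minute (cpm) per well. Raw cpm are calibrated to a unitless antibody index

    index = (mean sample cpm - mean blank cpm)
            / (mean positive-control cpm - mean blank cpm)

so the blank mean maps to 0 and the positive-control antibody to 1.
Duplicate wells are averaged before the formula. Positivity cutoffs are
mean + k * SD of the non-case control indices (k = 3 by default, with
per-antigen overrides such as k = 6 for very clean backgrounds); group
differences use Mann-Whitney U, cross-assay agreement uses Pearson
correlation, and dual-antigen agreement is a simple concordance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "antibody_index",
    "antibody_index_table",
    "positivity_call",
    "group_difference",
    "correlate_assays",
    "concordance",
    "read_rlba_table",
]

BLANK_ID = "BLANK"
POSCTRL_ID = "POSCTRL"

RLBA_COLUMNS = ["antigen", "sample_id", "replicate", "cpm"]


class DegenerateAssayError(ValueError):
    """Positive control does not exceed the blank — the assay carries no signal."""


def antibody_index(
    sample_cpms, blank_cpms, positive_cpms
) -> float:
    """Antibody index of one serum: (sample - blank) / (positive - blank), on means.

    Replicate wells are averaged first. The index may be negative when the
    sample signal falls below the blank; negative values are retained (they
    only matter relative to cutoffs).
    """
    sample = float(np.mean(np.asarray(sample_cpms, dtype=float)))
    blank = float(np.mean(np.asarray(blank_cpms, dtype=float)))
    positive = float(np.mean(np.asarray(positive_cpms, dtype=float)))
    if positive <= blank:
        raise DegenerateAssayError(
            f"positive-control mean ({positive:g} cpm) must exceed blank mean "
            f"({blank:g} cpm)"
        )
    return (sample - blank) / (positive - blank)


def antibody_index_table(rlba: pd.DataFrame) -> pd.DataFrame:
    """Antibody indices for every (antigen, sample) in a long-format well table.

    ``rlba`` columns: antigen, sample_id, replicate, cpm; blank wells carry
    sample_id ``BLANK`` and positive-control wells ``POSCTRL``. Every antigen
    must have at least one blank and one positive-control well.
    """
    missing = [c for c in RLBA_COLUMNS if c not in rlba.columns]
    if missing:
        raise ValueError(f"RLBA table missing columns: {missing}")
    if (rlba["cpm"] < 0).any():
        raise ValueError("cpm values must be non-negative")
    rows = []
    for antigen, grp in rlba.groupby("antigen", sort=True):
        blanks = grp.loc[grp["sample_id"] == BLANK_ID, "cpm"]
        pos = grp.loc[grp["sample_id"] == POSCTRL_ID, "cpm"]
        if blanks.empty or pos.empty:
            raise ValueError(
                f"antigen {antigen!r} needs >=1 blank and >=1 positive-control well"
            )
        sera = grp[~grp["sample_id"].isin([BLANK_ID, POSCTRL_ID])]
        for sample, wells in sera.groupby("sample_id", sort=True):
            idx = antibody_index(wells["cpm"], blanks, pos)
            rows.append((antigen, sample, idx))
    return pd.DataFrame(rows, columns=["antigen", "sample_id", "index"])


@dataclass
class PositivityCall:
    """Positivity flags with the cutoff that produced them."""

    flags: pd.Series  # bool per sample
    cutoff: float
    k_sd: float


def positivity_call(
    indices: pd.Series,
    control_indices: pd.Series | np.ndarray,
    k_sd: float = 3.0,
) -> PositivityCall:
    """Flag samples whose index exceeds mean(controls) + k_sd * SD(controls).

    Sample (n-1) standard deviation; strictly greater than the cutoff counts
    as positive (an index exactly at the cutoff is negative). Needs >= 2
    control indices for the SD to be defined.
    """
    controls = np.asarray(control_indices, dtype=float)
    if controls.size < 2:
        raise ValueError("need >= 2 control indices to define an SD cutoff")
    cutoff = float(controls.mean() + k_sd * controls.std(ddof=1))
    flags = indices > cutoff
    return PositivityCall(flags=flags, cutoff=cutoff, k_sd=k_sd)


def positivity_calls(
    index_table: pd.DataFrame,
    control_ids: list[str],
    k_sd: float = 3.0,
    antigen_overrides: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-antigen positivity over an index table, honouring k_sd overrides.

    Returns the index table with added columns cutoff, k_sd, positive. The
    control distribution for each antigen is its indices among ``control_ids``.
    """
    antigen_overrides = antigen_overrides or {}
    out = []
    for antigen, grp in index_table.groupby("antigen", sort=True):
        k = float(antigen_overrides.get(antigen, k_sd))
        ctrl = grp.loc[grp["sample_id"].isin(control_ids), "index"]
        call = positivity_call(grp.set_index("sample_id")["index"], ctrl, k_sd=k)
        g = grp.copy()
        g["cutoff"] = call.cutoff
        g["k_sd"] = k
        g["positive"] = call.flags.to_numpy()
        out.append(g)
    return pd.concat(out, ignore_index=True)


def group_difference(indices: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between case and control index distributions.

    ``labels`` maps sample to 'case'/'control'. Exact p for small samples,
    normal approximation with tie correction otherwise (scipy's default
    switching rule). Returns (U statistic of the case group, p).
    """
    labels = labels.reindex(indices.index)
    case = indices[labels == "case"].to_numpy()
    control = indices[labels == "control"].to_numpy()
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both case and control groups must be non-empty")
    res = stats.mannwhitneyu(case, control, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def correlate_assays(
    rlba_indices: pd.Series, phip_folds: pd.Series
) -> tuple[float, int]:
    """Pearson correlation between RLBA indices and PhIP-Seq enrichments.

    The two series are aligned on their (sample) index; only paired samples
    enter. Returns (r, n pairs). Constant input on either axis leaves the
    correlation undefined and raises.
    """
    common = rlba_indices.index.intersection(phip_folds.index)
    x = rlba_indices.loc[common].astype(float)
    y = phip_folds.loc[common].astype(float)
    keep = x.notna() & y.notna()
    x, y = x[keep].to_numpy(), y[keep].to_numpy()
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: Pearson correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r), int(len(x))


def concordance(
    pos_a: pd.Series, pos_b: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Fraction of shared samples with the same positivity status for two antigens.

    Returns (fraction concordant, 2x2 contingency table with antigen-A status
    as rows and antigen-B status as columns).
    """
    common = pos_a.index.intersection(pos_b.index)
    if len(common) == 0:
        raise ValueError("no shared samples between the two positivity vectors")
    a = pos_a.loc[common].astype(bool)
    b = pos_b.loc[common].astype(bool)
    frac = float((a == b).mean())
    table = pd.crosstab(a, b).reindex(index=[False, True], columns=[False, True],
                                      fill_value=0)
    return frac, table


def read_rlba_table(path) -> pd.DataFrame:
    """Read the long-format RLBA well CSV (antigen, sample_id, replicate, cpm)."""
    table = pd.read_csv(path)
    missing = [c for c in RLBA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"RLBA CSV missing columns: {missing}")
    return table
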