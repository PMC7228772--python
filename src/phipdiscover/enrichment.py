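"""Peptide- and gene-level PhIP-Seq enrichment over a mock-IP background.

The central statistic of a PhIP-Seq serology screen is the fold-change of a
peptide's (or gene's) share of sequencing reads in a serum immunoprecipitation
relative to the mean share observed in beads-only mock immunoprecipitations.
This module takes a raw tile x sample count matrix and a tile annotation
(which 49-AA tile belongs to which gene, at which protein coordinates) and
produces:

* read-percentage normalization (each sample column rescaled to sum to 100),
* gene-level aggregation of tile percentages,
* fold-change enrichment over the mock-IP mean, with a depth-derived
  pseudocount so zero backgrounds stay finite,
* per-protein epitope profiles (coordinate-ordered tile enrichments and a
  count of reactive tiles, a proxy for polyclonality).

Sample roles (case / control / mock) always come from an explicit sample
sheet; they are never inferred from sample names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "EpitopeProfile",
    "normalize_to_percent",
    "aggregate_by_gene",
    "fold_change",
    "pseudocount_from_depths",
    "peptide_profile",
    "read_count_matrix",
    "read_library",
    "read_sample_sheet",
    "validate_library",
]

ROLES = ("case", "control", "mock")
COHORTS = ("discovery", "validation", "none")

LIBRARY_COLUMNS = ["tile_id", "gene", "protein_id", "start", "end"]


class DegenerateSampleError(ValueError):
    """A sample column is unusable (e.g. zero total reads)."""


@dataclass
class CountMatrix:
    """Raw integer read counts (tile x sample) plus sample metadata.

    ``roles`` maps each sample id to case/control/mock; ``cohort`` maps each
    sample id to discovery/validation/none. At least one mock sample is
    required: the mock-IP columns define the background every enrichment is
    measured against.
    """

    counts: pd.DataFrame
    roles: pd.Series
    cohort: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cohort is None:
            self.cohort = pd.Series("none", index=self.counts.columns)
        self.roles = self.roles.reindex(self.counts.columns)
        self.cohort = self.cohort.reindex(self.counts.columns).fillna("none")
        if self.roles.isna().any():
            missing = list(self.roles.index[self.roles.isna()])
            raise ValueError(f"samples missing a role assignment: {missing}")
        bad = set(self.roles.unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        bad = set(self.cohort.unique()) - set(COHORTS)
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")
        if (self.roles == "mock").sum() < 1:
            raise ValueError("count matrix must contain at least one mock-IP sample")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        zero = self.counts.sum(axis=0) == 0
        if zero.any():
            raise DegenerateSampleError(
                f"samples with zero total reads: {list(self.counts.columns[zero])}"
            )

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def sample_ids(self, role: str, cohort: str | None = None) -> list[str]:
        """Sample ids with the given role (optionally restricted to a cohort)."""
        keep = self.roles == role
        if cohort is not None:
            keep &= self.cohort == cohort
        return list(self.counts.columns[keep])

    @property
    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)


def validate_library(library: pd.DataFrame) -> pd.DataFrame:
    """Check a tile annotation table and return it indexed by tile_id.

    Requires columns tile_id, gene, protein_id, start, end with 1-based
    inclusive protein coordinates and unique tile ids.
    """
    missing = [c for c in LIBRARY_COLUMNS if c not in library.columns]
    if missing:
        raise ValueError(f"library annotation missing columns: {missing}")
    lib = library.copy()
    if lib["tile_id"].duplicated().any():
        dups = lib.loc[lib["tile_id"].duplicated(), "tile_id"].tolist()
        raise ValueError(f"duplicate tile ids in library: {dups[:5]}")
    if (lib["start"] < 1).any() or (lib["end"] < lib["start"]).any():
        raise ValueError("tile coordinates must satisfy 1 <= start <= end")
    return lib.set_index("tile_id", drop=False)


def normalize_to_percent(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Convert raw counts to percentage of total reads per sample.

    Each column is rescaled so its entries sum to 100. A zero-total column is
    a degenerate sample and raises rather than silently producing NaN.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = mat.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise DegenerateSampleError(
            f"cannot normalize zero-read samples: {list(mat.columns[zero])}"
        )
    return 100.0 * mat / totals


def aggregate_by_gene(
    norm: pd.DataFrame, library: pd.DataFrame, mode: str = "sum"
) -> pd.DataFrame:
    """Pool tile-level percentages into gene-level values.

    Default mode ``sum`` (a gene's share of reads is the sum of its member
    tiles' shares, so gene columns still sum to 100); ``max`` takes the
    strongest tile per gene instead, for sensitivity analysis.
    """
    lib = library if library.index.name == "tile_id" else validate_library(library)
    orphans = norm.index.difference(lib.index)
    if len(orphans) > 0:
        raise ValueError(
            f"{len(orphans)} tiles have no library annotation: {list(orphans[:5])}"
        )
    genes = lib.loc[norm.index, "gene"]
    grouped = norm.groupby(genes.to_numpy())
    if mode == "sum":
        out = grouped.sum()
    elif mode == "max":
        out = grouped.max()
    else:
        raise ValueError(f"unknown aggregation mode {mode!r} (use 'sum' or 'max')")
    out.index.name = "gene"
    return out.sort_index()


def pseudocount_from_depths(mock_depths: pd.Series | np.ndarray) -> float:
    """Percentage equivalent of a single read at the median mock-IP depth."""
    depths = np.asarray(mock_depths, dtype=float)
    if depths.size == 0 or not np.all(depths > 0):
        raise ValueError("mock depths must be a non-empty positive vector")
    return 100.0 / float(np.median(depths))


def fold_change(
    values: pd.DataFrame,
    mock_ids: list[str],
    *,
    epsilon: float | None = None,
    mock_depths: pd.Series | None = None,
    background: str = "mean",
) -> pd.DataFrame:
    """Fold-change of read percentage over the mock-IP background.

    fold = (value + eps) / (mock background + eps), where the background is
    the mean (default; optionally median) of the mock-IP percentages and eps
    is the percentage equivalent of one read at the median mock sequencing
    depth. Mock columns are dropped from the output.

    Parameters
    ----------
    values : gene-or-tile x sample read percentages.
    mock_ids : sample ids of the mock-IP columns (must be non-empty).
    epsilon : pseudocount in percent units; computed from ``mock_depths``
        when not given.
    mock_depths : total read counts of the mock samples, used to derive
        ``epsilon`` when it is not supplied explicitly.
    """
    mock_ids = list(mock_ids)
    if len(mock_ids) == 0:
        raise ValueError("fold_change requires at least one mock-IP sample")
    missing = [m for m in mock_ids if m not in values.columns]
    if missing:
        raise ValueError(f"mock samples absent from value matrix: {missing}")
    if epsilon is None:
        if mock_depths is None:
            raise ValueError("provide either epsilon or mock_depths")
        epsilon = pseudocount_from_depths(mock_depths.loc[mock_ids])
    if epsilon < 0:
        raise ValueError("pseudocount must be non-negative")
    mocks = values[mock_ids]
    if background == "mean":
        bg = mocks.mean(axis=1)
    elif background == "median":
        bg = mocks.median(axis=1)
    else:
        raise ValueError(f"unknown background {background!r} (use 'mean' or 'median')")
    rest = values.drop(columns=mock_ids)
    fold = (rest + epsilon).div(bg + epsilon, axis=0)
    fold.attrs["epsilon"] = epsilon
    return fold


@dataclass
class EpitopeProfile:
    """Per-tile enrichment along one protein, ordered by start coordinate."""

    gene: str
    tiles: pd.DataFrame  # columns: tile_id, start, end, plus one column per sample
    threshold: float
    n_reactive_tiles: pd.Series  # per sample: tiles with fold >= threshold


def peptide_profile(
    gene: str,
    tile_fold: pd.DataFrame,
    library: pd.DataFrame,
    threshold: float = 10.0,
) -> EpitopeProfile:
    """Map tile-level enrichment across the full length of one protein.

    Returns the gene's tiles sorted by protein start coordinate together with
    the per-sample count of tiles at or above ``threshold`` — the number of
    independently enriched sites, a proxy for polyclonality of the response.
    """
    lib = library if library.index.name == "tile_id" else validate_library(library)
    members = lib[lib["gene"] == gene].reset_index(drop=True)
    if members.empty:
        raise KeyError(f"gene {gene!r} not present in the peptide library")
    members = members.sort_values(["start", "tile_id"], kind="mergesort")
    members = members.set_index("tile_id", drop=False)
    present = [t for t in members["tile_id"] if t in tile_fold.index]
    if not present:
        raise KeyError(f"no tiles of gene {gene!r} found in the enrichment matrix")
    folds = tile_fold.loc[present]
    tiles = pd.concat(
        [members.loc[present, ["tile_id", "start", "end"]].reset_index(drop=True),
         folds.reset_index(drop=True)],
        axis=1,
    )
    n_reactive = (folds >= threshold).sum(axis=0)
    return EpitopeProfile(gene=gene, tiles=tiles, threshold=threshold,
                          n_reactive_tiles=n_reactive)


# ---------------------------------------------------------------------------
# Readers for the external file formats
# ---------------------------------------------------------------------------

def read_count_matrix(counts_path, sample_sheet_path) -> CountMatrix:
    """Load a tile x sample count TSV plus a sample-sheet CSV.

    The count TSV has tile_id as its first column and one integer column per
    sample; the sample sheet is a CSV with columns sample_id, role, cohort
    (and optionally sex).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = read_sample_sheet(sample_sheet_path)
    unknown = counts.columns.difference(sheet.index)
    if len(unknown) > 0:
        raise ValueError(f"samples missing from sample sheet: {list(unknown)}")
    return CountMatrix(
        counts=counts,
        roles=sheet["role"],
        cohort=sheet["cohort"] if "cohort" in sheet else None,
    )


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    if "sample_id" not in sheet.columns or "role" not in sheet.columns:
        raise ValueError("sample sheet needs columns sample_id and role")
    sheet = sheet.set_index("sample_id")
    if "cohort" not in sheet.columns:
        sheet["cohort"] = "none"
    return sheet


def read_library(path) -> pd.DataFrame:
    """Load and validate the tile annotation TSV."""
    return validate_library(pd.read_csv(path, sep="\t"))
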