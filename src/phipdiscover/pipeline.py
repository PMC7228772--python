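"""End-to-end orchestration: simulate or ingest, enrich, call, test, report.

A single seeded ``RunConfig`` drives the whole discovery analysis:

    counts -> read-percentage normalization -> gene aggregation
           -> fold-change over mock-IP mean -> 10-fold positivity
           -> candidate antigens (known >= 2 cases, novel >= 3 cases,
              0 control positives) -> known/novel partition, frequency
              ranking, clustered z-matrix
           -> tissue-specificity resampling test on the candidates
           -> KS phenotype-association screen with directional masking
           -> RLBA antibody indices, cutoffs, group tests, cross-assay
              correlation, dual-antigen concordance

Every artifact lands under the configured output directory together with a
resolved-config snapshot, a log, and a SHA-256 manifest; re-running with the
same config and seed reproduces the payloads byte for byte. Inputs are never
mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, hits, phenotypes as phen_mod, rlba as rlba_mod, tissue
from .enrichment import CountMatrix
from .synthetic import SimulationConfig, SyntheticStudy, simulate_study

__all__ = ["RunConfig", "ReportBundle", "run_discovery", "make_fixtures"]

log = logging.getLogger("phipdiscover")

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Resolved configuration of one discovery run (fully serializable)."""

    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    # input paths (used when simulate is False)
    counts_path: str | None = None
    library_path: str | None = None
    sample_sheet_path: str | None = None
    phenotype_path: str | None = None
    expression_path: str | None = None
    expression_format: str = "wide"  # or "hpa"
    rlba_path: str | None = None
    known_antigens_path: str | None = None
    # thresholds (defaults encode the discovery criteria)
    fold_threshold: float = 10.0
    min_cases_known: int = 2
    min_cases_novel: int = 3
    max_controls: int = 0
    aggregation: str = "sum"
    background: str = "mean"
    # downstream statistics
    n_iter: int = 10_000
    k_sd: float = 3.0
    k_sd_overrides: dict = field(default_factory=dict)
    alpha_mask: float = 0.05
    min_group_size: int = 3
    bh_adjust: bool = False
    write_tile_folds: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReportBundle:
    """In-memory results of one run plus the paths of everything written."""

    config: RunConfig
    gene_fold: pd.DataFrame
    candidates: pd.DataFrame          # gene, n_case_pos, n_control_pos, known_flag
    known: list[str]
    novel: list[str]
    ranking: pd.DataFrame
    zmatrix: pd.DataFrame | None
    row_order: list[str]
    col_order: list[str]
    specificity: tissue.SpecificityResult | None
    associations: pd.DataFrame | None
    rlba_indices: pd.DataFrame | None
    rlba_comparison: dict | None
    artifacts: dict[str, str] = field(default_factory=dict)  # name -> sha256


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    """Return (counts, library, phenotypes, sex_specific, expression, rlba, truth)."""
    if config.simulate:
        sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
        study = simulate_study(sim)
        log.info("simulated study: %d tiles, %d genes, %d samples",
                 len(study.library), study.library["gene"].nunique(),
                 study.counts.counts.shape[1])
        return (study.counts, study.library, study.phenotypes, {},
                study.expression, study.rlba, study)
    required = {"counts_path": config.counts_path,
                "library_path": config.library_path,
                "sample_sheet_path": config.sample_sheet_path}
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ValueError(f"non-simulation run needs paths for: {missing}")
    counts = enrichment.read_count_matrix(config.counts_path,
                                          config.sample_sheet_path)
    library = enrichment.read_library(config.library_path)
    phen, sex_specific = (None, {})
    if config.phenotype_path:
        phen, sex_specific = phen_mod.read_phenotype_table(config.phenotype_path)
    expr = None
    if config.expression_path:
        reader = (tissue.read_expression_hpa if config.expression_format == "hpa"
                  else tissue.read_expression_wide)
        expr = reader(config.expression_path)
    rlba = rlba_mod.read_rlba_table(config.rlba_path) if config.rlba_path else None
    return counts, library, phen, sex_specific, expr, rlba, None


def run_discovery(config: RunConfig) -> ReportBundle:
    """Run the whole discovery pipeline and write a reproducible report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_discovery(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_discovery(config: RunConfig, out: Path) -> ReportBundle:
    counts, library, phen, sex_specific, expr, rlba_table, study = \
        _load_inputs(config)

    # --- enrichment -------------------------------------------------------
    norm = enrichment.normalize_to_percent(counts)
    gene_pct = enrichment.aggregate_by_gene(norm, library, mode=config.aggregation)
    mock_ids = counts.sample_ids("mock")
    gene_fold = enrichment.fold_change(
        gene_pct, mock_ids, mock_depths=counts.depths, background=config.background)
    tile_fold = enrichment.fold_change(
        norm, mock_ids, mock_depths=counts.depths, background=config.background)
    log.info("fold-change over %d mock-IPs (pseudocount %.3g%%), %d genes",
             len(mock_ids), gene_fold.attrs["epsilon"], gene_fold.shape[0])

    # --- hit calling ------------------------------------------------------
    pos = hits.call_positive_genes(gene_fold, threshold=config.fold_threshold)
    cand_known_set = hits.candidate_antigens(
        pos, counts.roles, min_cases=config.min_cases_known,
        max_controls=config.max_controls, cohort=counts.cohort)
    cand_novel_set = hits.candidate_antigens(
        pos, counts.roles, min_cases=config.min_cases_novel,
        max_controls=config.max_controls, cohort=counts.cohort)
    if config.known_antigens_path:
        known_list = {line.strip() for line in
                      Path(config.known_antigens_path).read_text().splitlines()
                      if line.strip() and not line.startswith("#")}
    elif config.simulate and study is not None:
        known_list = set(study.truth.antigen_genes)  # truth stands in for literature
    else:
        known_list = hits.load_known_antigens()
    known, novel = hits.cross_reference_known(cand_novel_set, known_list)
    candidates = cand_novel_set.table.copy()
    candidates["known_flag"] = candidates["gene"].isin(known_list)
    ranking = hits.rank_by_frequency(pos, counts.roles, cohort=counts.cohort)
    log.info("candidates: %d at >=%d cases (known criteria: %d at >=%d)",
             len(cand_novel_set), config.min_cases_novel,
             len(cand_known_set), config.min_cases_known)

    zmatrix, row_order, col_order = None, [], []
    if len(candidates) >= 2:
        zmatrix, row_order, col_order, flagged = hits.zscore_and_cluster(
            gene_fold, genes=list(candidates["gene"]))
        if flagged:
            log.info("zero-variance rows placed last in clustering: %s", flagged)

    # --- tissue specificity ----------------------------------------------
    specificity = None
    if expr is not None and len(candidates) >= 2:
        try:
            specificity = tissue.resampling_enrichment_test(
                set(candidates["gene"]), expr, n_iter=config.n_iter,
                seed=config.seed)
            log.info("tissue restriction: %.2f-fold vs null, p=%.4g",
                     specificity.fold_vs_null, specificity.empirical_p)
        except tissue.InsufficientDataError as err:
            log.warning("tissue-specificity test skipped: %s", err)

    # --- phenotype associations -------------------------------------------
    associations = None
    if phen is not None and len(candidates) >= 1 and phen.shape[1] >= 1:
        case_ids = counts.sample_ids("case")
        associations = phen_mod.association_screen(
            gene_fold[ [s for s in case_ids if s in gene_fold.columns] ],
            phen, genes=list(candidates["gene"]),
            min_group_size=config.min_group_size,
            alpha_mask=config.alpha_mask, bh_adjust=config.bh_adjust,
            sex_specific=sex_specific)
        log.info("association screen: %d gene x phenotype tests",
                 len(associations))

    # --- RLBA --------------------------------------------------------------
    rlba_indices, rlba_comparison = None, None
    if rlba_table is not None and len(rlba_table) > 0:
        index_table = rlba_mod.antibody_index_table(rlba_table)
        control_ids = counts.sample_ids("control")
        rlba_indices = rlba_mod.positivity_calls(
            index_table, control_ids, k_sd=config.k_sd,
            antigen_overrides=config.k_sd_overrides)
        rlba_comparison = _compare_assays(rlba_indices, gene_fold, counts)
        log.info("RLBA: %d antigens, %d indices", index_table["antigen"].nunique(),
                 len(index_table))

    bundle = ReportBundle(
        config=config, gene_fold=gene_fold, candidates=candidates,
        known=known, novel=novel, ranking=ranking, zmatrix=zmatrix,
        row_order=row_order, col_order=col_order, specificity=specificity,
        associations=associations, rlba_indices=rlba_indices,
        rlba_comparison=rlba_comparison)
    _write_report(bundle, out, tile_fold if config.write_tile_folds else None,
                  study)
    return bundle


def _compare_assays(rlba_indices: pd.DataFrame, gene_fold: pd.DataFrame,
                    counts: CountMatrix) -> dict:
    """Mann-Whitney, PhIP correlation, and pairwise concordance per antigen."""
    discovery_cases = set(counts.sample_ids("case", cohort="discovery"))
    roles = counts.roles
    comparison: dict = {"antigens": {}, "concordance": {}}
    flags = {}
    for antigen, grp in rlba_indices.groupby("antigen", sort=True):
        idx = grp.set_index("sample_id")["index"]
        entry: dict = {"cutoff": float(grp["cutoff"].iloc[0]),
                       "k_sd": float(grp["k_sd"].iloc[0]),
                       "n_positive": int(grp["positive"].sum())}
        try:
            U, p = rlba_mod.group_difference(idx, roles)
            entry["mannwhitney_U"], entry["mannwhitney_p"] = U, p
        except ValueError as err:
            entry["mannwhitney_error"] = str(err)
        if antigen in gene_fold.index:
            paired = idx[idx.index.isin(discovery_cases)]
            try:
                r, n = rlba_mod.correlate_assays(paired, gene_fold.loc[antigen])
                entry["pearson_r"], entry["pearson_n"] = r, n
            except ValueError as err:
                entry["pearson_error"] = str(err)
        flags[antigen] = grp.set_index("sample_id")["positive"]
        comparison["antigens"][antigen] = entry
    names = sorted(flags)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                frac, table = rlba_mod.concordance(flags[a], flags[b])
            except ValueError:
                continue
            comparison["concordance"][f"{a}|{b}"] = {
                "fraction": frac, "table": table.to_numpy().tolist()}
    return comparison


def _write_report(bundle: ReportBundle, out: Path,
                  tile_fold: pd.DataFrame | None,
                  study: SyntheticStudy | None) -> None:
    cfg = bundle.config
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, index: bool) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
        written.append(path)

    save_df(bundle.gene_fold, "gene_fold_change.tsv", index=True)
    if tile_fold is not None:
        save_df(tile_fold, "tile_fold_change.tsv", index=True)
    save_df(bundle.candidates, "candidates.tsv", index=False)
    save_df(bundle.ranking, "frequency_ranking.tsv", index=False)
    if bundle.zmatrix is not None:
        save_df(bundle.zmatrix, "zscore_matrix.tsv", index=True)
        order_path = out / "cluster_orders.json"
        order_path.write_text(json.dumps(
            {"rows": bundle.row_order, "columns": bundle.col_order}, indent=1))
        written.append(order_path)
    if bundle.specificity is not None:
        path = out / "tissue_specificity.json"
        path.write_text(json.dumps(bundle.specificity.to_dict(), indent=1))
        written.append(path)
    if bundle.associations is not None:
        save_df(bundle.associations, "associations.tsv", index=False)
    if bundle.rlba_indices is not None:
        save_df(bundle.rlba_indices, "rlba_indices.tsv", index=False)
    if bundle.rlba_comparison is not None:
        path = out / "rlba_comparison.json"
        path.write_text(json.dumps(bundle.rlba_comparison, indent=1))
        written.append(path)
    if study is not None:
        save_df(study.truth_table(), "truth_table.tsv", index=False)

    snap = out / "config_snapshot.yaml"
    snap.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    written.append(snap)

    bundle.artifacts = {p.name: _sha256(p) for p in written}
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps(bundle.artifacts, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

FIXTURE_SCALES = {
    "tiny": dict(n_genes=20, n_cases=6, n_controls=4, n_mock=3,
                 reads_per_sample=50_000, n_planted=3, tiles_per_gene_target=4,
                 n_phenotypes=6, reactive_cases_range=(3, 5)),
    "paper-like": dict(),  # the defaults are already the study-scale design
}


def make_fixtures(out_dir, scale: str = "tiny", seed: int = 0) -> dict[str, Path]:
    """Write a complete synthetic input file set (plus truth table) to disk.

    ``tiny`` is a 20-gene, 6+4+3-sample study for unit tests; ``paper-like``
    uses the full default design (39/28/17 samples, 200 genes). Emits the
    same TSV/CSV formats the readers consume.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(**FIXTURE_SCALES[scale], seed=seed)
    study = simulate_study(config)

    paths = {}

    def put(name: str, writer) -> None:
        path = out / name
        writer(path)
        paths[name] = path

    put("counts.tsv", lambda p: study.counts.counts.to_csv(p, sep="\t"))
    put("library.tsv", lambda p: study.library.to_csv(p, sep="\t", index=False))
    put("samples.csv", lambda p: pd.DataFrame({
        "sample_id": study.counts.samples,
        "role": study.counts.roles.to_numpy(),
        "cohort": study.counts.cohort.to_numpy(),
    }).to_csv(p, index=False))
    put("phenotypes.csv", lambda p: study.phenotypes.to_csv(p))
    put("expression.tsv", lambda p: study.expression.to_csv(
        p, sep="\t", float_format=FLOAT_FMT))
    put("rlba.csv", lambda p: study.rlba.to_csv(p, index=False,
                                                float_format=FLOAT_FMT))
    put("truth.tsv", lambda p: study.truth_table().to_csv(p, sep="\t", index=False))
    return paths
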