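"""Synthetic PhIP-Seq studies with known ground truth.

Every downstream stage of the pipeline is testable without the deposited
sequencing data because this module generates a complete study — tiled
peptide library, case/control/mock count matrices, clinical phenotypes,
tissue expression, and RLBA well plates — from a single seeded
configuration, together with the planted truth the pipeline must recover.

The sequencing model: each tile has a log-normal base phage abundance
(heavy-tailed library representation, realistic dropout at finite depth);
a serum's two rounds of amplification + immunoprecipitation are collapsed
into one net multiplicative enrichment factor applied to the epitope tiles
of the antigens that serum reacts to; each sample's counts are then a
single multinomial draw of ``reads_per_sample`` over the weighted tiles.
Mock-IP samples never receive enrichment. Sequence content is uniform
random — nothing downstream reads amino acids, only coordinates.

Default cohort sizes mirror a realistic discovery study in this disease
(39 cases / 28 controls / 17 mock-IPs) so simulated power matches the
regime the thresholds were designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import CountMatrix

__all__ = [
    "SyntheticProteome",
    "PlantedTruth",
    "SimulationConfig",
    "SyntheticStudy",
    "random_proteome",
    "tile_proteome",
    "make_planted_truth",
    "simulate_counts",
    "simulate_phenotypes",
    "simulate_expression",
    "simulate_rlba",
    "latent_from_fold",
    "simulate_study",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: penetrance / background disease rate for phenotypes linked to an antigen
DEFAULT_PENETRANCE = 0.9
DEFAULT_BACKGROUND_RATE = 0.05
#: prevalence of unlinked (nuisance) phenotypes among cases
UNLINKED_PREVALENCE = 0.3
#: clinical manifestations per phenotype table
DEFAULT_N_PHENOTYPES = 24

#: RLBA plate defaults (cpm scale of a scintillation readout)
DEFAULT_BLANK_CPM = 250.0
DEFAULT_POSITIVE_CPM = 25_000.0
DEFAULT_RLBA_NOISE_SD = 250.0


@dataclass(frozen=True)
class SyntheticProteome:
    """One synthetic protein: an identifier, a gene symbol, and a sequence."""

    protein_id: str
    gene: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"protein {self.protein_id} has empty sequence")


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: which antigens are reactive in whom.

    enrichment_factor is the net multiplicative phage enrichment the serum
    IP confers on the antigen's epitope tiles (dimensionless, > 1).
    phenotype_links maps phenotype name -> (antigen, penetrance,
    background_rate).
    """

    antigen_genes: list[str]
    reactive_map: dict[str, list[str]]          # antigen -> case sample ids
    epitope_map: dict[str, list[str]]           # antigen -> reactive tile ids
    enrichment_factor: dict[str, float]
    phenotype_links: dict[str, tuple[str, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, f in self.enrichment_factor.items():
            if f <= 1:
                raise ValueError(f"enrichment factor for {gene} must be > 1, got {f}")
        for name, (_, pen, bg) in self.phenotype_links.items():
            if not (0 <= bg <= pen <= 1):
                raise ValueError(
                    f"phenotype {name}: need 0 <= background <= penetrance <= 1"
                )

    def to_table(self) -> pd.DataFrame:
        """Long truth table (antigen, sample, tile, factor) for test assertions."""
        rows = []
        for gene in self.antigen_genes:
            factor = self.enrichment_factor[gene]
            for sample in self.reactive_map.get(gene, []):
                for tile in self.epitope_map.get(gene, []):
                    rows.append((gene, sample, tile, factor))
        return pd.DataFrame(rows, columns=["antigen", "sample", "tile", "factor"])


@dataclass
class SimulationConfig:
    """All knobs of a synthetic study; one seed makes every output reproducible."""

    n_cases: int = 39
    n_controls: int = 28
    n_mock: int = 17
    reads_per_sample: int = 1_000_000
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.0
    n_genes: int = 200
    tiles_per_gene_target: int = 8
    n_planted: int = 10
    epitope_fraction: float = 0.75
    enrichment_factor_range: tuple[float, float] = (30.0, 300.0)
    reactive_cases_range: tuple[int, int] = (5, 15)
    n_phenotypes: int = DEFAULT_N_PHENOTYPES
    n_tissues: int = 74
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_mock", "reads_per_sample",
                     "n_genes", "tiles_per_gene_target"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.epitope_fraction <= 1):
            raise ValueError("epitope_fraction must be in (0, 1]")
        if self.n_planted < 0 or self.n_planted > self.n_genes:
            raise ValueError("n_planted must be between 0 and n_genes")
        lo, hi = self.enrichment_factor_range
        if not (1 < lo <= hi):
            raise ValueError("enrichment_factor_range must satisfy 1 < lo <= hi")

    def sample_ids(self) -> tuple[list[str], list[str], list[str]]:
        cases = [f"CASE-{i + 1:03d}" for i in range(self.n_cases)]
        controls = [f"CTRL-{i + 1:03d}" for i in range(self.n_controls)]
        mocks = [f"MOCK-{i + 1:03d}" for i in range(self.n_mock)]
        return cases, controls, mocks


# ---------------------------------------------------------------------------
# Library
# ---------------------------------------------------------------------------

def random_proteome(config: SimulationConfig,
                    rng: np.random.Generator) -> list[SyntheticProteome]:
    """Uniform-random protein sequences sized to hit the target tile count.

    Protein lengths are jittered around the length that yields
    ``tiles_per_gene_target`` tiles at 49/25 tiling, including a random
    sub-step remainder so C-terminus-anchored final tiles are exercised.
    """
    step = 49 - 25
    proteins = []
    for i in range(config.n_genes):
        k = int(rng.integers(max(1, config.tiles_per_gene_target - 3),
                             config.tiles_per_gene_target + 4))
        length = 49 + step * (k - 1) + int(rng.integers(0, step))
        seq = "".join(rng.choice(AMINO_ACIDS, size=length))
        proteins.append(SyntheticProteome(
            protein_id=f"PROT{i + 1:04d}", gene=f"GENE{i + 1:04d}", sequence=seq))
    return proteins


def tile_proteome(
    proteome: list[SyntheticProteome], tile_len: int = 49, overlap: int = 25
) -> pd.DataFrame:
    """Tile each protein into fixed-length windows with the given overlap.

    Windows start at residue 1 and advance by ``tile_len - overlap`` (24 for
    the defaults). Whenever the last regular window stops short of the
    C-terminus a final window anchored to the C-terminus is added, so every
    residue is covered and all tiles of a long protein keep the full length
    (trailing residues get duplicated coverage instead of padding). Proteins
    shorter than ``tile_len`` yield a single full-protein tile. Coordinates
    are 1-based inclusive.
    """
    if tile_len <= overlap or overlap < 0:
        raise ValueError("require tile_len > overlap >= 0")
    step = tile_len - overlap
    rows = []
    for prot in proteome:
        L = prot.length
        if L <= tile_len:
            windows = [(1, L)]
        else:
            starts = list(range(1, L - tile_len + 2, step))
            windows = [(s, s + tile_len - 1) for s in starts]
            if windows[-1][1] < L:
                windows.append((L - tile_len + 1, L))
        for j, (s, e) in enumerate(windows, start=1):
            rows.append((f"{prot.protein_id}_t{j:03d}", prot.gene,
                         prot.protein_id, s, e, e - s + 1))
    lib = pd.DataFrame(rows, columns=["tile_id", "gene", "protein_id",
                                      "start", "end", "tile_len"])
    return lib.set_index("tile_id", drop=False)


# ---------------------------------------------------------------------------
# Planted truth and counts
# ---------------------------------------------------------------------------

def make_planted_truth(
    config: SimulationConfig,
    library: pd.DataFrame,
    rng: np.random.Generator,
) -> PlantedTruth:
    """Choose antigens, their epitope tiles, reactive cases, and phenotype links.

    Antigens are drawn without replacement from the library's genes; each
    gets a log-uniform net enrichment factor, a fixed epitope tile set
    (``epitope_fraction`` of its tiles, at least one), and a reactive case
    subset sized uniformly within ``reactive_cases_range``. Each antigen is
    linked to one phenotype (penetrance 0.9, background 0.05 by default).
    """
    genes = sorted(library["gene"].unique())
    if config.n_planted > len(genes):
        raise ValueError("more planted antigens requested than genes in library")
    cases, _, _ = config.sample_ids()
    antigens = sorted(str(g) for g in
                      rng.choice(genes, size=config.n_planted, replace=False))
    lo, hi = config.enrichment_factor_range
    factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_planted))
    reactive_map, epitope_map, factor_map, links = {}, {}, {}, {}
    r_lo, r_hi = config.reactive_cases_range
    r_hi = min(r_hi, len(cases))
    for gene, factor in zip(antigens, factors):
        tiles = library.loc[library["gene"] == gene, "tile_id"].tolist()
        k = max(1, int(round(config.epitope_fraction * len(tiles))))
        epitope_map[gene] = sorted(
            str(t) for t in rng.choice(tiles, size=k, replace=False))
        n_reactive = int(rng.integers(r_lo, r_hi + 1))
        reactive_map[gene] = sorted(
            str(s) for s in rng.choice(cases, size=n_reactive, replace=False))
        factor_map[gene] = float(factor)
    for i, gene in enumerate(antigens):
        links[f"PHEN-{i + 1:02d}"] = (gene, DEFAULT_PENETRANCE,
                                      DEFAULT_BACKGROUND_RATE)
    return PlantedTruth(
        antigen_genes=list(antigens),
        reactive_map=reactive_map,
        epitope_map=epitope_map,
        enrichment_factor=factor_map,
        phenotype_links=links,
    )


def simulate_counts(
    config: SimulationConfig,
    library: pd.DataFrame,
    truth: PlantedTruth,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Multinomial sequencing counts for every case, control, and mock sample.

    Per-tile weights = log-normal base abundance, multiplied by the
    antigen's enrichment factor on its epitope tiles in the case samples
    that react to it. Each column is one multinomial draw of
    ``reads_per_sample`` over the renormalized weights; columns therefore
    sum exactly to the read depth. Controls and mocks never receive
    enrichment.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tile_ids = library.index
    tile_pos = {t: i for i, t in enumerate(tile_ids)}
    for gene, tiles in truth.epitope_map.items():
        missing = [t for t in tiles if t not in tile_pos]
        if missing:
            raise ValueError(
                f"epitope tiles of {gene} absent from library: {missing[:5]}")
        gene_tiles = set(library.loc[library["gene"] == gene, "tile_id"])
        stray = [t for t in tiles if t not in gene_tiles]
        if stray:
            raise ValueError(
                f"epitope tiles of {gene} belong to other genes: {stray[:5]}")

    base = rng.lognormal(config.abundance_logmean, config.abundance_logsd,
                         size=len(tile_ids))
    cases, controls, mocks = config.sample_ids()

    enrich_of = {s: [] for s in cases}
    for gene, samples in truth.reactive_map.items():
        idx = np.fromiter((tile_pos[t] for t in truth.epitope_map[gene]), dtype=int)
        f = truth.enrichment_factor[gene]
        for s in samples:
            enrich_of[s].append((idx, f))

    columns = {}
    for s in cases + controls + mocks:
        w = base.copy()
        for idx, f in enrich_of.get(s, []):
            w[idx] *= f
        columns[s] = rng.multinomial(config.reads_per_sample, w / w.sum())
    counts = pd.DataFrame(columns, index=tile_ids)
    roles = pd.Series(
        {**{s: "case" for s in cases}, **{s: "control" for s in controls},
         **{s: "mock" for s in mocks}})
    cohort = pd.Series(
        {**{s: "discovery" for s in cases + controls}, **{s: "none" for s in mocks}})
    return CountMatrix(counts=counts, roles=roles, cohort=cohort)


# ---------------------------------------------------------------------------
# Phenotypes, expression, RLBA
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    truth: PlantedTruth,
    case_ids: list[str],
    rng: np.random.Generator,
    n_phenotypes: int | None = None,
    unlinked_prevalence: float = UNLINKED_PREVALENCE,
) -> pd.DataFrame:
    """Binary clinical phenotypes for the case cohort.

    Phenotypes linked to a planted antigen affect its reactive cases with
    probability = penetrance and everyone else with probability =
    background_rate. Remaining phenotypes (up to ``n_phenotypes`` total) are
    unlinked noise at a fixed prevalence.
    """
    for name, (antigen, pen, bg) in truth.phenotype_links.items():
        if antigen not in truth.antigen_genes:
            raise ValueError(f"phenotype {name} links unknown antigen {antigen}")
        if not (0 <= pen <= 1 and 0 <= bg <= 1):
            raise ValueError(f"phenotype {name}: rates must lie in [0, 1]")
    data = {}
    for name in sorted(truth.phenotype_links):
        antigen, pen, bg = truth.phenotype_links[name]
        reactive = set(truth.reactive_map.get(antigen, []))
        p = np.where([s in reactive for s in case_ids], pen, bg)
        data[name] = (rng.random(len(case_ids)) < p).astype(int)
    total = n_phenotypes if n_phenotypes is not None else max(
        DEFAULT_N_PHENOTYPES, len(data))
    for j in range(len(data), total):
        data[f"BG-{j + 1:02d}"] = (
            rng.random(len(case_ids)) < unlinked_prevalence).astype(int)
    return pd.DataFrame(data, index=pd.Index(case_ids, name="sample_id"))


def simulate_expression(
    genes: list[str],
    n_tissues: int = 74,
    restricted_genes: set[str] | None = None,
    rng: np.random.Generator | None = None,
    restricted_mass: tuple[float, float] = (0.92, 0.98),
) -> pd.DataFrame:
    """Gene x tissue consensus-style expression with known restriction.

    Restricted genes concentrate a fraction of their expression mass (drawn
    from ``restricted_mass``) in one random tissue; broad genes draw
    near-uniform positive values, so their max/sum ratio sits near
    1/n_tissues. All entries are non-negative.
    """
    rng = rng if rng is not None else np.random.default_rng()
    restricted_genes = restricted_genes or set()
    unknown = restricted_genes - set(genes)
    if unknown:
        raise ValueError(f"restricted genes not in gene list: {sorted(unknown)[:5]}")
    tissues = [f"tissue_{t + 1:02d}" for t in range(n_tissues)]
    rows = np.empty((len(genes), n_tissues))
    for i, gene in enumerate(genes):
        row = rng.uniform(0.6, 1.4, size=n_tissues)
        if gene in restricted_genes:
            mass = rng.uniform(*restricted_mass)
            major = int(rng.integers(n_tissues))
            others = row.sum() - row[major]
            row[major] = mass / (1.0 - mass) * others
            row *= 100.0 / row.sum()  # normalized-TPM-like scale
        rows[i] = row
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=tissues)


def latent_from_fold(fold, half_saturation: float = 50.0):
    """Monotone map from PhIP-Seq fold-change to a latent [0, 1) reactivity.

    A saturating fold / (fold + K) curve: background folds near 1 map to
    ~1/(1+K) while strongly enriched antigens approach 1, mimicking how an
    RLBA signal saturates against its positive control.
    """
    f = np.maximum(np.asarray(fold, dtype=float), 0.0)
    out = f / (f + half_saturation)
    if isinstance(fold, pd.Series):
        return pd.Series(out, index=fold.index)
    return out


def simulate_rlba(
    latent_reactivity: pd.Series,
    antigen: str = "ANTIGEN",
    noise_sd: float = DEFAULT_RLBA_NOISE_SD,
    blank_cpm: float = DEFAULT_BLANK_CPM,
    positive_cpm: float = DEFAULT_POSITIVE_CPM,
    n_replicates: int = 2,
    n_blanks: int = 4,
    n_positive: int = 2,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format RLBA well table for one antigen.

    Expected serum-well cpm is the affine interpolation
    blank + latent * (positive - blank); every well (sera in duplicate,
    blanks, positive controls) gets independent Gaussian noise and is
    floored at zero counts.
    """
    if positive_cpm <= blank_cpm:
        raise ValueError("positive_cpm must exceed blank_cpm")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    rows = []

    def wells(sample_id: str, expected: float, n: int) -> None:
        cpm = expected + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 \
            else np.full(n, expected)
        for rep, value in enumerate(cpm, start=1):
            rows.append((antigen, sample_id, rep, max(0.0, float(value))))

    for sample, latent in latent_reactivity.items():
        if not (0.0 <= latent <= 1.0):
            raise ValueError(f"latent reactivity of {sample} outside [0, 1]")
        wells(sample, blank_cpm + latent * (positive_cpm - blank_cpm), n_replicates)
    wells("BLANK", blank_cpm, n_blanks)
    wells("POSCTRL", positive_cpm, n_positive)
    return pd.DataFrame(rows, columns=["antigen", "sample_id", "replicate", "cpm"])


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Everything one seeded simulation produces, plus its ground truth."""

    config: SimulationConfig
    library: pd.DataFrame
    counts: CountMatrix
    truth: PlantedTruth
    phenotypes: pd.DataFrame
    expression: pd.DataFrame
    rlba: pd.DataFrame  # long well table over the planted antigens

    def truth_table(self) -> pd.DataFrame:
        return self.truth.to_table()


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full synthetic study from one config; pure in (config, seed).

    Stage order (proteome -> truth -> counts -> phenotypes -> expression ->
    RLBA) each consumes its own child stream of the config seed, so the
    whole bundle is bit-reproducible.
    """
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]

    proteome = random_proteome(config, rngs[0])
    library = tile_proteome(proteome)
    truth = make_planted_truth(config, library, rngs[1])
    counts = simulate_counts(config, library, truth, rngs[2])
    cases, controls, _ = config.sample_ids()
    phenotypes = simulate_phenotypes(truth, cases, rngs[3],
                                     n_phenotypes=config.n_phenotypes)
    expression = simulate_expression(
        sorted(library["gene"].unique()), n_tissues=config.n_tissues,
        restricted_genes=set(truth.antigen_genes), rng=rngs[4])

    # RLBA over the planted antigens: latent reactivity is a saturating,
    # slightly noisy function of the planted state (strong for reactive
    # cases, background otherwise), measured for cases and controls.
    rlba_rng = rngs[5]
    tables = []
    sera = cases + controls
    for gene in truth.antigen_genes:
        reactive = set(truth.reactive_map[gene])
        lat = np.where([s in reactive for s in sera],
                       latent_from_fold(truth.enrichment_factor[gene]), 0.02)
        lat = np.clip(lat + rlba_rng.normal(0, 0.02, size=len(sera)), 0.0, 1.0)
        tables.append(simulate_rlba(pd.Series(lat, index=sera), antigen=gene,
                                    rng=rlba_rng))
    rlba = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["antigen", "sample_id", "replicate", "cpm"])

    return SyntheticStudy(config=config, library=library, counts=counts,
                          truth=truth, phenotypes=phenotypes,
                          expression=expression, rlba=rlba)
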