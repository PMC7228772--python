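import numpy as np
import pandas as pd
import pytest

from phipdiscover import CountMatrix, SimulationConfig, simulate_study

TINY = dict(
    n_genes=40, n_cases=6, n_controls=4, n_mock=3, reads_per_sample=50_000,
    n_planted=3, tiles_per_gene_target=4, n_phenotypes=6,
    reactive_cases_range=[3, 5],
)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(**TINY, seed=11)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


@pytest.fixture(scope="session")
def paper_like_study():
    """Default-design study: 39 cases / 28 controls / 17 mocks, 200 genes."""
    return simulate_study(SimulationConfig(seed=5))


@pytest.fixture()
def toy_library() -> pd.DataFrame:
    return pd.DataFrame({
        "tile_id": ["t1", "t2", "t3", "t4", "t5"],
        "gene": ["g1", "g1", "g2", "g3", "g3"],
        "protein_id": ["p1", "p1", "p2", "p3", "p3"],
        "start": [1, 25, 1, 1, 25],
        "end": [49, 73, 49, 49, 73],
    })


@pytest.fixture()
def toy_counts() -> CountMatrix:
    """5 tiles x 4 samples (1 case, 1 control, 2 mocks), printed integers."""
    counts = pd.DataFrame(
        {
            "S1": [900, 50, 30, 15, 5],
            "S2": [200, 300, 250, 150, 100],
            "M1": [210, 290, 240, 160, 100],
            "M2": [190, 310, 260, 140, 100],
        },
        index=["t1", "t2", "t3", "t4", "t5"],
    )
    roles = pd.Series({"S1": "case", "S2": "control", "M1": "mock", "M2": "mock"})
    return CountMatrix(counts=counts, roles=roles)


def brute_force_gene_folds(counts: pd.DataFrame, tile_gene: dict[str, str],
                           mock_ids: list[str]) -> dict[tuple[str, str], float]:
    """Plain-Python oracle: percentages -> gene sums -> fold over mock mean.

    Deliberately loop-based and independent of the library code paths.
    """
    samples = list(counts.columns)
    totals = {s: sum(counts[s][t] for t in counts.index) for s in samples}
    pct = {(t, s): 100.0 * counts[s][t] / totals[s]
           for t in counts.index for s in samples}
    genes = sorted(set(tile_gene.values()))
    gene_pct = {(g, s): sum(pct[(t, s)] for t in counts.index if tile_gene[t] == g)
                for g in genes for s in samples}
    depths = sorted(totals[m] for m in mock_ids)
    n = len(depths)
    median = (depths[n // 2] if n % 2 else
              0.5 * (depths[n // 2 - 1] + depths[n // 2]))
    eps = 100.0 / median
    folds = {}
    for g in genes:
        mock_mean = sum(gene_pct[(g, m)] for m in mock_ids) / len(mock_ids)
        for s in samples:
            if s in mock_ids:
                continue
            folds[(g, s)] = (gene_pct[(g, s)] + eps) / (mock_mean + eps)
    return folds
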