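import numpy as np
import pandas as pd
import pytest

from allelescan.genomes import Panel
from allelescan.pipeline import RunConfig, run_pipeline
from allelescan.synthetic import SimParams, generate_panel, simulate_all


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic study (seed 1), in memory only."""
    return simulate_all(seed=1)


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory):
    """A full pipeline run (seed 1) from files on disk."""
    out = tmp_path_factory.mktemp("run1")
    funnel, tables = run_pipeline(RunConfig(seed=1), str(out))
    return out, funnel, tables


@pytest.fixture(scope="session")
def small_panel():
    """A small dense panel for unit tests (all-common AF)."""
    gp = generate_panel(
        n_samples=4,
        n_sites=60,
        af_spectrum=("uniform", 0.2, 0.8),
        chrom_length=30_000,
        seed=7,
        margin=200,
    )
    return gp.panel


def toy_panel(haps: np.ndarray, chrom_length: int = 1000) -> Panel:
    """Panel with explicit haplotypes, shape (n_sites, n_samples, 2)."""
    n_sites, n_samples, _ = haps.shape
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, chrom_length))
    pos = np.linspace(100, chrom_length - 100, n_sites).astype(int)
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos + 1,
            "id": [f"s{i}" for i in range(n_sites)],
            "ref": [seq[p] for p in pos],
            "alt": ["ACGT"[("ACGT".index(seq[p]) + 1) % 4] for p in pos],
        }
    )
    return Panel(
        samples=[f"S{i}" for i in range(n_samples)],
        reference={"chr1": seq},
        sites=sites,
        haplotypes=haps.astype(np.int8),
    )
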