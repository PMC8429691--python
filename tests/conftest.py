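import numpy as np
import pandas as pd
import pytest

from refugia.geno_io import GenotypeMatrix, PopulationTable
from refugia.pipeline import default_candidates
from refugia.synthetic_data import SynthConfig, generate_dataset


def make_genotypes(rng: np.random.Generator, n_samples: int, n_snps: int,
                   missing_rate: float = 0.1, n_chrom: int = 2) -> GenotypeMatrix:
    """Random valid genotype matrix for round-trip and filter tests."""
    calls = rng.integers(0, 3, size=(n_samples, n_snps)).astype(float)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan
    per = np.array_split(np.arange(n_snps), n_chrom)
    chrom = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=int)
    for ci, idx in enumerate(per, start=1):
        chrom[idx] = str(ci)
        pos[idx] = np.arange(1, len(idx) + 1) * 100
    snps = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "id": [f"s{c}_{p}" for c, p in zip(chrom, pos)],
    })
    return GenotypeMatrix(
        samples=[f"ind{i}" for i in range(n_samples)], snps=snps, calls=calls
    )


def make_pops(members: dict[str, list[str]],
              coords: dict[str, tuple[float, float]] | None = None,
              mean_bp: dict[str, float] | None = None) -> PopulationTable:
    rows = []
    membership = {}
    for pop, sams in members.items():
        x, y = (coords or {}).get(pop, (0.0, 0.0))
        bp = (mean_bp or {}).get(pop, 0.0)
        rows.append(dict(pop_id=pop, longitude=x, latitude=y, mean_bp=bp,
                         interval_lo=bp - 1000 if bp else np.nan,
                         interval_hi=bp + 1000 if bp else np.nan,
                         group=""))
        for s in sams:
            membership[s] = pop
    table = pd.DataFrame(rows).set_index("pop_id")
    return PopulationTable(table=table, membership=pd.Series(membership))


@pytest.fixture(scope="session")
def small_dataset():
    """One cached mid-size synthetic dataset shared across tests."""
    cfg = SynthConfig(seed=42, n_snps=2000, n_modern=4, n_ancient=5,
                      true_model=default_candidates()[0])
    return generate_dataset(cfg)
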