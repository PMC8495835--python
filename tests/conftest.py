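"""Shared fixtures: tiny hand-built datasets and seeded synthetic scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from haplopop import (
    Dataset,
    GenotypeMatrix,
    MicrohapLocus,
    SampleMetadata,
    sim_island_locus,
)
from haplopop.simulate import EstuarySpec, ScenarioConfig, generate


@pytest.fixture
def toy_geno() -> GenotypeMatrix:
    """2 loci x 3 individuals, fully observed."""
    loci = [
        MicrohapLocus("L1", "c1", 2, ("AA", "AT", "TT")),
        MicrohapLocus("L2", "c2", 3, ("ACG", "ACT")),
    ]
    calls = np.array([
        [[0, 1], [1, 2], [0, 0]],
        [[0, 0], [0, 1], [1, 1]],
    ])
    return GenotypeMatrix(["i1", "i2", "i3"], loci, calls)


@pytest.fixture
def toy_dataset(toy_geno) -> Dataset:
    meta = [
        SampleMetadata("i1", "estA", "gulf", "yoy", 10.0),
        SampleMetadata("i2", "estA", "gulf", "adult", 10.0),
        SampleMetadata("i3", "estB", "gulf", "yoy", 200.0),
    ]
    return Dataset(genotypes=toy_geno, metadata=meta)


@pytest.fixture(scope="session")
def gulf_scenario():
    """Single-basin scenario with planted environmental signal (shared)."""
    ests = [EstuarySpec(f"E{i}", "gulf", i * 100.0, 18) for i in range(8)]
    cfg = ScenarioConfig(estuaries=ests, n_loci=120, frac_env_loci=0.1,
                         beta_env=3.0, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def twobasin_scenario():
    """Small two-basin scenario for structure analyses (shared)."""
    ests = (
        [EstuarySpec(f"G{i}", "gulf", i * 120.0, 14) for i in range(4)]
        + [EstuarySpec(f"A{i}", "atlantic", 2000.0 + i * 120.0, 14) for i in range(3)]
    )
    cfg = ScenarioConfig(estuaries=ests, n_loci=100, frac_env_loci=0.0, seed=5)
    return generate(cfg)


def island_genotypes(n_pops: int, copies_per_pop: int, d: int, M: float,
                     n_loci: int, rng: np.random.Generator,
                     theta: float = 1.0) -> tuple[GenotypeMatrix, list[str]]:
    """Island-model genotype matrix + population labels (package helper)."""
    from haplopop.simulate import island_genotypes as _ig

    return _ig(n_pops, copies_per_pop, d, M, n_loci, rng, theta=theta)
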