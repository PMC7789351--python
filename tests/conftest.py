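"""Shared fixtures and brute-force oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from creprime import (
    AnalysisConfig,
    Peak,
    PeakSet,
    SyntheticParams,
    generate_dataset,
)


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def dataset():
    """One deterministic noise-free synthetic study, shared across tests."""
    return generate_dataset(SyntheticParams(seed=11))


@pytest.fixture(scope="session")
def small_params() -> SyntheticParams:
    """Reduced-size parameters for tests that regenerate many datasets."""
    return SyntheticParams(
        n_chroms=2,
        chrom_length=500_000,
        n_genes=30,
        n_common_peaks=30,
        n_exclusive_per_lineage=10,
        n_unique_per_lineage=8,
        n_stem_unique=8,
        n_background=25,
        seed=0,
    )


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive; independent of the library's
# sweep/index machinery)


def brute_overlaps(a: Peak, b: Peak) -> bool:
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def brute_overlap_pairs(a: list[Peak], b: list[Peak]) -> set[tuple[int, int]]:
    return {
        (i, j)
        for i, pa in enumerate(a)
        for j, pb in enumerate(b)
        if brute_overlaps(pa, pb)
    }


def random_peaks(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    span: int = 5_000,
    max_width: int = 400,
    prefix: str = "p",
) -> list[Peak]:
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        score = float(np.round(rng.uniform(0, 100), 3))
        peaks.append(Peak(chrom, start, start + width, f"{prefix}{i}", score))
    return peaks


def random_peakset(
    rng: np.random.Generator, label: str, n: int, **kw
) -> PeakSet:
    return PeakSet(label, random_peaks(rng, n, prefix=f"{label}_", **kw))
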