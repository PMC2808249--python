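"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bathyrule.tables import SpeciesRecord, SpeciesTable


def rec(
    name: str,
    genus: str = "Genus",
    length: float = 100.0,
    dmin: float = 10.0,
    dmax: float = 50.0,
) -> SpeciesRecord:
    return SpeciesRecord(
        taxon_name=name,
        genus=genus,
        shell_length_mm=length,
        depth_min_m=dmin,
        depth_max_m=dmax,
    )


def random_genus(
    rng: np.random.Generator,
    n_deep: int,
    n_shallow: int,
    genus: str = "G",
) -> tuple[list[SpeciesRecord], list[SpeciesRecord]]:
    """A genus with continuous random lengths and midpoints (no ties)."""
    deep = []
    for i in range(n_deep):
        lo = rng.uniform(450, 1500)
        deep.append(
            rec(f"{genus} d{i}", genus, float(rng.lognormal(3, 1)), lo, lo + rng.uniform(10, 500))
        )
    shallow = []
    for i in range(n_shallow):
        lo = rng.uniform(0, 90)
        shallow.append(
            rec(f"{genus} s{i}", genus, float(rng.lognormal(3, 1)), lo, lo + rng.uniform(5, 100))
        )
    return deep, shallow


def groups_from(*genera) -> dict:
    return {d[0].genus: (list(d), list(s)) for d, s in genera}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture
def small_table() -> SpeciesTable:
    """Three genera, each with deep and shallow members."""
    records = [
        rec("Abra alba", "Abra", 12.0, 5, 80),
        rec("Abra nitida", "Abra", 20.0, 10, 150),
        rec("Abra profunda", "Abra", 8.0, 500, 900),
        rec("Buccinum undatum", "Buccinum", 90.0, 0, 120),
        rec("Buccinum abyssorum", "Buccinum", 60.0, 600, 1400),
        rec("Conus magus", "Conus", 45.0, 2, 40),
        rec("Conus profundorum", "Conus", 30.0, 450, 700),
    ]
    return SpeciesTable(records=records, source="fixture")
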