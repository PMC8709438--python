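"""Shared fixtures: small deterministic assemblies and call tables."""

import numpy as np
import pandas as pd
import pytest

from rlmeth import (
    GeneFeature,
    GenomeAssembly,
    MethylationTable,
    Replicon,
)
from rlmeth.synthetic_data import make_genome


@pytest.fixture(scope="session")
def small_assembly() -> GenomeAssembly:
    """Two-replicon random genome at realistic rhizobial GC (seeded)."""
    return make_genome({"chr": 10_000, "p1": 2_000}, 61.0, seed=42)


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    """Hand-written linear assembly for exact coordinate arithmetic."""
    return GenomeAssembly(
        replicons=(
            Replicon("chr", "GATCGATCAA" * 100, topology="linear"),
            Replicon("p1", "GGCGCCATAT" * 50, topology="linear"),
        ),
        chromosome_name="chr",
    )


@pytest.fixture
def toy_genes() -> list[GeneFeature]:
    return [
        GeneFeature("g1", "chr", 200, 500, "+", frozenset({"L"})),
        GeneFeature("g2", "chr", 600, 900, "-", frozenset({"E", "K"})),
        GeneFeature("g3", "p1", 50, 400, "+", frozenset()),
    ]


def make_table(condition: str, rows: list[tuple]) -> MethylationTable:
    """Rows: (replicon, position, strand, base, mod_type, coverage, modified)."""
    df = pd.DataFrame(rows, columns=["replicon", "position", "strand",
                                     "base", "mod_type", "coverage",
                                     "modified"])
    return MethylationTable(condition=condition, sites=df)


@pytest.fixture
def uniform_table(toy_assembly) -> MethylationTable:
    """Every A/C site of toy chr at coverage 10, 50% methylated."""
    rows = []
    seq = toy_assembly.get("chr").sequence
    comp = {"A": ("+", "A"), "T": ("-", "A"), "C": ("+", "C"),
            "G": ("-", "C")}
    for pos, b in enumerate(seq):
        strand, base = comp[b]
        mod = "6mA" if base == "A" else "4mC"
        rows.append(("chr", pos, strand, base, mod, 10, 5))
    return make_table("uniform", rows)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20210928)
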