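"""Shared fixtures: toy usage tables and small synthetic host pairs."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from codonharmony import (
    CodingSequence,
    CodonUsageTable,
    STANDARD_CODE,
    counts_to_rca,
    simulate_host,
)
from codonharmony.synthetic import SyntheticHostSpec


@pytest.fixture
def make_table():
    """Factory for hand-specified usage tables.

    ``counts`` gives explicit per-codon counts; every other codon gets
    ``fill`` (default 1, so unspecified families have uniform RCA 1 and
    no zero entries distract from the family under test).
    """

    def _make(counts: dict[str, int], fill: int = 1, pseudo_rule: str = "zero",
              host_label: str = "toy") -> CodonUsageTable:
        full = {codon: fill for codon in STANDARD_CODE.codon_to_aa}
        full.update(counts)
        table = CodonUsageTable(
            host_label=host_label,
            counts=full,
            n_cds=1,
            n_codons=sum(full.values()),
            pseudo_rule=pseudo_rule,
        )
        return counts_to_rca(table)

    return _make


@pytest.fixture(scope="session")
def host_pair():
    """Two small synthetic hosts with different codon preferences."""
    table_a, cds_a = simulate_host(
        SyntheticHostSpec(seed=101, skew=3.0, n_cds=120, mean_len_codons=120)
    )
    table_b, cds_b = simulate_host(
        SyntheticHostSpec(seed=202, skew=1.5, n_cds=120, mean_len_codons=120)
    )
    return (table_a, cds_a), (table_b, cds_b)


def random_cds(rng: np.random.Generator, n_codons: int) -> CodingSequence:
    """A random valid CDS: ATG start, random interior, random stop."""
    aas = [aa for aa in STANDARD_CODE.families if aa != "*"]
    codons = ["ATG"]
    for _ in range(max(0, n_codons - 2)):
        fam = STANDARD_CODE.families[rng.choice(aas)]
        codons.append(fam[rng.integers(len(fam))])
    codons.append(STANDARD_CODE.families["*"][rng.integers(3)])
    return CodingSequence(label="random", dna="".join(codons))


def enumerate_synonymous_variants(seq: CodingSequence):
    """Yield every synonymous variant of ``seq`` as a codon list."""
    families = [STANDARD_CODE.synonymous_codons(c) for c in seq.codons]
    yield from itertools.product(*families)
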