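"""Seeded synthetic hosts and genes for testing without genome downloads.

A synthetic host is a set of per-family codon preferences drawn from a
symmetric Dirichlet whose concentration is controlled by a single
``skew`` knob: 0 gives exactly uniform usage within every family, large
values concentrate usage on one dominant codon per family (stop codons
included, so stop-handling paths are exercised). A CDS collection is
then sampled codon-wise from those preferences — start ATG, uniform
amino-acid composition in the interior, a sampled stop at the end — and
the returned usage table is rebuilt from the emitted CDS, so counts,
fractions and RCA are self-consistent by construction.

What this emulates: per-family codon bias of real genomes, at
controllable strength. What it does not: amino-acid composition bias,
GC gradients, codon-pair effects, gene-length distributions of real
genomes — conclusions about those cannot be drawn from these fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_code import GeneticCode, STANDARD_CODE, STOP_SYMBOL
from .io import CodingSequence
from .usage_tables import CodonUsageTable, build_table


@dataclass(frozen=True)
class SyntheticHostSpec:
    """Parameters of a synthetic host genome.

    ``skew`` >= 0 sets the concentration of per-family preference
    (0 = uniform; 2 is a typical moderately biased genome; >10 nearly
    one codon per family). ``n_cds`` and ``mean_len_codons`` default to
    a small genome sample: 500 CDS of ~300 codons, enough to pin
    per-family fractions to a few percent.
    """

    seed: int
    skew: float = 2.0
    n_cds: int = 500
    mean_len_codons: int = 300

    def __post_init__(self) -> None:
        if self.skew < 0:
            raise ValueError("skew must be >= 0")
        if self.n_cds < 1 or self.mean_len_codons < 3:
            raise ValueError("need n_cds >= 1 and mean_len_codons >= 3")


def _family_probabilities(
    rng: np.random.Generator, code: GeneticCode, skew: float
) -> dict[str, np.ndarray]:
    """Per-family codon probabilities; Dirichlet(1/skew) unless uniform."""
    probs = {}
    for aa, fam in code.families.items():
        k = len(fam)
        if skew == 0 or k == 1:
            probs[aa] = np.full(k, 1.0 / k)
        else:
            probs[aa] = rng.dirichlet(np.full(k, 1.0 / skew))
    return probs


def simulate_host(
    spec: SyntheticHostSpec, code: GeneticCode = STANDARD_CODE
) -> tuple[CodonUsageTable, list[CodingSequence]]:
    """Draw a host's codon preferences and sample a CDS collection.

    Returns the usage table rebuilt from the emitted CDS together with
    the CDS themselves. Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fam_probs = _family_probabilities(rng, code, spec.skew)
    amino_acids = sorted(aa for aa in code.families if aa != STOP_SYMBOL)
    stops = code.families[STOP_SYMBOL]

    records: list[CodingSequence] = []
    for g in range(spec.n_cds):
        n_interior = max(1, int(rng.poisson(spec.mean_len_codons - 2)))
        aas = rng.choice(amino_acids, size=n_interior)
        codons = ["ATG"]
        for aa in aas:
            fam = code.families[aa]
            codons.append(fam[rng.choice(len(fam), p=fam_probs[aa])])
        codons.append(stops[rng.choice(len(stops), p=fam_probs[STOP_SYMBOL])])
        records.append(
            CodingSequence(
                label=f"synth_cds_{g + 1:05d}",
                dna="".join(codons),
                source_file=f"simulate_host(seed={spec.seed})",
            )
        )
    table = build_table(
        [(r.label, r.dna) for r in records],
        code=code,
        host_label=f"synthetic host (seed={spec.seed}, skew={spec.skew})",
    )
    return table, records


def simulate_gene(
    native_table: CodonUsageTable, length_codons: int, seed: int
) -> CodingSequence:
    """Sample a wild-type-like gene from a host's codon usage.

    Interior amino acids are drawn proportional to the host's per-
    family totals and codons within each family proportional to the
    host's counts, so sampled codon frequencies converge to the table's
    family fractions. The gene is a valid CDS: ATG start, sampled stop,
    ``length_codons`` codons in total (minimum 3).
    """
    if length_codons < 3:
        raise ValueError("a CDS needs at least start, one codon, and stop")
    if not native_table.rca:
        raise ValueError("table needs RCA scores; run counts_to_rca first")
    rng = np.random.default_rng(seed)
    code = native_table.code
    amino_acids = sorted(aa for aa in code.families if aa != STOP_SYMBOL)
    aa_weights = np.array(
        [
            sum(native_table.counts.get(c, 0) for c in code.families[aa])
            for aa in amino_acids
        ],
        dtype=float,
    )
    if aa_weights.sum() == 0:
        aa_weights[:] = 1.0
    aa_probs = aa_weights / aa_weights.sum()

    def draw_codon(aa: str) -> str:
        fam = code.families[aa]
        weights = np.array([native_table.counts.get(c, 0) for c in fam], dtype=float)
        probs = weights / weights.sum() if weights.sum() else np.full(len(fam), 1 / len(fam))
        return fam[rng.choice(len(fam), p=probs)]

    codons = ["ATG"]
    for aa in rng.choice(amino_acids, size=length_codons - 2, p=aa_probs):
        codons.append(draw_codon(aa))
    codons.append(draw_codon(STOP_SYMBOL))
    return CodingSequence(
        label=f"synthetic_gene_seed{seed}",
        dna="".join(codons),
        source_file=f"simulate_gene(seed={seed})",
    )
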