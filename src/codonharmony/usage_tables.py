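"""Host codon-usage tables and relative codon adaptiveness (RCA).

A :class:`CodonUsageTable` holds, for one host genome, the raw codon
counts X_ij accumulated over every codon of every protein-coding gene,
the per-family maxima X_imax, and the derived RCA scores

    RCA(codon) = X_ij / X_imax,

i.e. a codon's count divided by the count of the most frequent codon of
its synonymous family. RCA is 1.0 for each family's preferred codon and
falls toward 0 for rare codons. Unlike the classical codon adaptation
index of Sharp & Li, which references a small set of highly expressed
genes, these scores are computed from *all* annotated CDS of a genome.

Stop codons are counted as an ordinary three-member family; whether
downstream metrics include them is decided there, not here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .genetic_code import (
    ALL_CODONS,
    GeneticCode,
    SequenceError,
    STANDARD_CODE,
    codons_of,
    normalize_dna,
)

logger = logging.getLogger(__name__)

PseudoRule = Literal["zero", "sharp_half"]


@dataclass
class CodonUsageTable:
    """Codon counts and RCA scores for one host.

    Attributes
    ----------
    host_label:
        Free-text host name carried through to file headers.
    counts:
        Codon -> non-negative count over all counted CDS.
    family_max:
        Amino-acid symbol -> count of the family's most frequent codon.
    rca:
        Codon -> relative codon adaptiveness in [0, 1]; empty until
        :func:`counts_to_rca` has run.
    pseudo_rule:
        How unobserved codons score: ``"zero"`` applies the count ratio
        literally (RCA 0); ``"sharp_half"`` scores them 0.5 / X_imax,
        the classical remedy that keeps geometric means off zero.
    """

    host_label: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    family_max: dict[str, int] = field(default_factory=dict)
    rca: dict[str, float] = field(default_factory=dict)
    n_cds: int = 0
    n_codons: int = 0
    pseudo_rule: PseudoRule = "zero"
    code: GeneticCode = STANDARD_CODE

    def family_fraction(self, codon: str) -> float:
        """Count fraction of ``codon`` within its synonymous family."""
        fam = self.code.synonymous_codons(codon)
        total = sum(self.counts.get(c, 0) for c in fam)
        return self.counts.get(codon, 0) / total if total else 1.0 / len(fam)


def build_codon_counts(
    cds_records: Iterable[str | tuple[str, str]],
    code: GeneticCode = STANDARD_CODE,
    strict: bool = False,
    host_label: str = "",
    pseudo_rule: PseudoRule = "zero",
) -> CodonUsageTable:
    """Count codons over a collection of CDS, reading frame 1 of each.

    Records may be plain DNA strings or ``(label, dna)`` pairs. In
    lenient mode (default) a trailing partial codon is dropped and
    codons containing non-ACGT characters are skipped, both logged; in
    strict mode either condition rejects the whole run, naming the
    record. Internal stop codons are counted as stops: genome CDS files
    carry annotation artifacts and genome-scale counting should not
    abort on them.
    """
    counts = {codon: 0 for codon in ALL_CODONS}
    n_cds = 0
    n_codons = 0
    empty = True
    for idx, record in enumerate(cds_records):
        empty = False
        label, dna = record if isinstance(record, tuple) else (f"record {idx + 1}", record)
        dna = normalize_dna(dna)
        if len(dna) % 3 != 0:
            if strict:
                raise SequenceError(
                    f"{label}: length {len(dna)} is not a multiple of 3"
                )
            logger.warning(
                "%s: dropping trailing partial codon (%d nt)", label, len(dna) % 3
            )
        for codon in codons_of(dna):
            if codon not in counts:
                if strict:
                    raise SequenceError(f"{label}: non-ACGT codon {codon!r}")
                logger.warning("%s: skipping non-ACGT codon %r", label, codon)
                continue
            counts[codon] += 1
            n_codons += 1
        n_cds += 1
    if empty:
        raise ValueError("no CDS records supplied")
    return CodonUsageTable(
        host_label=host_label,
        counts=counts,
        n_cds=n_cds,
        n_codons=n_codons,
        pseudo_rule=pseudo_rule,
        code=code,
    )


def counts_to_rca(table: CodonUsageTable) -> CodonUsageTable:
    """Fill ``family_max`` and ``rca`` from ``counts`` (returns a copy).

    For each family, RCA = count / family maximum. Unobserved codons
    score 0 under the ``zero`` rule or 0.5 / family_max under
    ``sharp_half``. An entirely unobserved family gets uniform RCA 1
    with a warning (no evidence distinguishes its codons).
    """
    family_max: dict[str, int] = {}
    rca: dict[str, float] = {}
    for aa, fam in table.code.families.items():
        fmax = max(table.counts.get(c, 0) for c in fam)
        family_max[aa] = fmax
        if fmax == 0:
            logger.warning(
                "family %s has no observed codons; assigning uniform RCA 1", aa
            )
            for c in fam:
                rca[c] = 1.0
            continue
        for c in fam:
            n = table.counts.get(c, 0)
            if n == 0 and table.pseudo_rule == "sharp_half":
                rca[c] = 0.5 / fmax
            else:
                rca[c] = n / fmax
    return replace(table, family_max=family_max, rca=rca)


def merge_tables(a: CodonUsageTable, b: CodonUsageTable) -> CodonUsageTable:
    """Element-wise sum of two count tables; RCA recomputed.

    Used when a genome's CDS arrive split over several files. Hosts
    with differing labels merge with a warning only.
    """
    if a.code.table_id != b.code.table_id:
        raise ValueError(
            f"cannot merge tables over different genetic codes "
            f"({a.code.table_id} vs {b.code.table_id})"
        )
    if a.host_label and b.host_label and a.host_label != b.host_label:
        logger.warning(
            "merging tables with different host labels: %r vs %r",
            a.host_label,
            b.host_label,
        )
    counts = {
        codon: a.counts.get(codon, 0) + b.counts.get(codon, 0)
        for codon in ALL_CODONS
    }
    merged = CodonUsageTable(
        host_label=a.host_label or b.host_label,
        counts=counts,
        n_cds=a.n_cds + b.n_cds,
        n_codons=a.n_codons + b.n_codons,
        pseudo_rule=a.pseudo_rule,
        code=a.code,
    )
    return counts_to_rca(merged)


def build_table(
    cds_records: Sequence[str | tuple[str, str]],
    code: GeneticCode = STANDARD_CODE,
    strict: bool = False,
    host_label: str = "",
    pseudo_rule: PseudoRule = "zero",
) -> CodonUsageTable:
    """Convenience: count codons and fill RCA in one call."""
    return counts_to_rca(
        build_codon_counts(
            cds_records,
            code=code,
            strict=strict,
            host_label=host_label,
            pseudo_rule=pseudo_rule,
        )
    )
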