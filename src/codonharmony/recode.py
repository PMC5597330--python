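"""Synonymous recoding: harmonization, a most-frequent baseline, motif removal.

Harmonization recodes a gene for an expression host so that each
position's relative codon adaptiveness (RCA) matches, as closely as the
expression host's synonymous family allows, the RCA the wild-type codon
has in the native host. Because CHI is a mean of independent
per-position terms, this greedy per-position choice is the exact CHI
minimizer over all synonymous variants. Frequent codons map to
frequent, rare to rare — preserving putative translational pause sites
rather than erasing them.

The most-frequent baseline replaces every codon with its family's
preferred (RCA 1) codon in the expression host. It is a transparent
stand-in for commercial multi-parameter optimizers, which additionally
weigh GC content, mRNA structure and other factors; it is documented
as such and is not equivalent to any of them.

Motif avoidance removes unwanted DNA motifs (typically restriction
sites) from a recoded sequence by stepping the offending codon to the
synonymous alternative with the next-closest RCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genetic_code import normalize_dna
from .io import CodingSequence
from .metrics import cai, chi, profile
from .usage_tables import CodonUsageTable

logger = logging.getLogger(__name__)

_REVCOMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(dna: str) -> str:
    return dna.translate(_REVCOMP)[::-1]


@dataclass(frozen=True)
class MotifConstraint:
    """DNA motifs to keep out of a designed sequence.

    With ``scan_both_strands`` (default) each motif is also searched as
    its reverse complement, since restriction enzymes recognize
    double-stranded sites.
    """

    motifs: frozenset[str]
    scan_both_strands: bool = True

    def __init__(self, motifs, scan_both_strands: bool = True) -> None:
        cleaned = frozenset(normalize_dna(m) for m in motifs)
        if not cleaned or any(not m or set(m) - set("ACGT") for m in cleaned):
            raise ValueError("motifs must be non-empty ACGT strings")
        object.__setattr__(self, "motifs", cleaned)
        object.__setattr__(self, "scan_both_strands", scan_both_strands)

    @property
    def search_set(self) -> frozenset[str]:
        if not self.scan_both_strands:
            return self.motifs
        return self.motifs | {reverse_complement(m) for m in self.motifs}


class MotifUnavoidableError(ValueError):
    """No synonymous substitution can remove a motif occurrence."""


@dataclass
class PositionRecord:
    """Per-codon trace of a recoding decision (1-based position)."""

    position: int
    input_codon: str
    output_codon: str
    rca_native: float
    rca_expr_chosen: float
    abs_delta: float


@dataclass
class RecodingResult:
    input_seq: CodingSequence
    output_seq: CodingSequence
    per_position: list[PositionRecord]
    chi_before: float | None
    chi_after: float | None
    cai_before: float
    cai_after: float
    substitutions_for_motifs: list[int] = field(default_factory=list)


def _ranked_candidates(
    codon: str,
    expr: CodonUsageTable,
    target_rca: float | None,
) -> list[str]:
    """Synonymous codons ranked by the recoding preference.

    With a ``target_rca`` (harmonization): ascending |RCA - target|,
    ties toward the higher expression-host RCA, then toward keeping the
    input codon, then alphabetical — keeping the input on exact ties
    makes self-harmonization an exact identity. Without a target
    (most-frequent baseline): descending RCA, ties alphabetical.
    """
    family = expr.code.synonymous_codons(codon)
    if target_rca is None:
        return sorted(family, key=lambda c: (-expr.rca[c], c))
    return sorted(
        family,
        key=lambda c: (abs(expr.rca[c] - target_rca), -expr.rca[c], c != codon, c),
    )


def _finalize(
    seq: CodingSequence,
    output_codons: list[str],
    native: CodonUsageTable | None,
    expr: CodonUsageTable,
    substitutions: list[int],
) -> RecodingResult:
    out_seq = CodingSequence(
        label=seq.label, dna="".join(output_codons), source_file=seq.source_file
    )
    per_position = []
    for i, (cin, cout) in enumerate(zip(seq.codons, output_codons)):
        r_native = native.rca[cin] if native is not None else float("nan")
        r_expr = expr.rca[cout]
        per_position.append(
            PositionRecord(
                position=i + 1,
                input_codon=cin,
                output_codon=cout,
                rca_native=r_native,
                rca_expr_chosen=r_expr,
                abs_delta=abs(r_expr - r_native) if native is not None else float("nan"),
            )
        )
    if native is not None:
        p_native = profile(seq, native)
        chi_before = chi(profile(seq, expr), p_native)
        chi_after = chi(profile(out_seq, expr), p_native)
    else:
        chi_before = chi_after = None
    return RecodingResult(
        input_seq=seq,
        output_seq=out_seq,
        per_position=per_position,
        chi_before=chi_before,
        chi_after=chi_after,
        cai_before=cai(profile(seq, expr)),
        cai_after=cai(profile(out_seq, expr)),
        substitutions_for_motifs=substitutions,
    )


def harmonize(
    seq: CodingSequence,
    native: CodonUsageTable,
    expr: CodonUsageTable,
    constraints: MotifConstraint | None = None,
) -> RecodingResult:
    """Recode ``seq`` so its RCA landscape in ``expr`` mimics the
    wild-type landscape in ``native``.

    For each position the output codon minimizes
    ``|RCA_expr(candidate) - RCA_native(input codon)|`` over the
    synonymous family. If ``constraints`` are given, a motif-removal
    pass follows (see :func:`avoid_motifs`).
    """
    if native.code.table_id != expr.code.table_id:
        raise ValueError("native and expression tables use different genetic codes")
    if not native.rca or not expr.rca:
        raise ValueError("both tables need RCA scores; run counts_to_rca first")
    output = [
        _ranked_candidates(codon, expr, native.rca[codon])[0] for codon in seq.codons
    ]
    result = _finalize(seq, output, native, expr, substitutions=[])
    if constraints is not None:
        result = avoid_motifs(result, constraints, native=native, expr=expr)
    return result


def recode_most_frequent(
    seq: CodingSequence,
    expr: CodonUsageTable,
    constraints: MotifConstraint | None = None,
) -> RecodingResult:
    """Replace every codon by its family's preferred codon in ``expr``.

    The resulting CAI is exactly 1. This is a deliberately transparent
    baseline, not a re-implementation of any commercial optimizer.
    """
    if not expr.rca:
        raise ValueError("table needs RCA scores; run counts_to_rca first")
    output = [_ranked_candidates(codon, expr, None)[0] for codon in seq.codons]
    result = _finalize(seq, output, None, expr, substitutions=[])
    if constraints is not None:
        result = avoid_motifs(result, constraints, native=None, expr=expr)
    return result


def find_motif_occurrences(dna: str, search_set) -> list[tuple[int, str]]:
    """All (0-based start, motif) occurrences, overlapping included."""
    hits = []
    for motif in search_set:
        start = dna.find(motif)
        while start != -1:
            hits.append((start, motif))
            start = dna.find(motif, start + 1)
    return sorted(hits)


def avoid_motifs(
    result: RecodingResult,
    constraints: MotifConstraint,
    native: CodonUsageTable | None,
    expr: CodonUsageTable,
) -> RecodingResult:
    """Remove forbidden motifs from a recoded sequence.

    The sequence (and, by default, its reverse complement via the
    mirrored motif set) is scanned left to right. For the leftmost
    occurrence, the codons it overlaps are tried left to right; at the
    first codon with remaining synonymous alternatives the next-closest
    RCA codon is substituted (then third-closest, and so on). A
    substitution is accepted only if it lowers the total motif count,
    so each pass strictly reduces occurrences and the loop terminates.
    Translation is never altered. Substituted codon positions (1-based)
    are appended to ``substitutions_for_motifs``.
    """
    codons = list(result.output_seq.codons)
    input_codons = result.input_seq.codons
    targets = [
        native.rca[c] if native is not None else None for c in input_codons
    ]
    ranked = [
        _ranked_candidates(cin, expr, t) for cin, t in zip(input_codons, targets)
    ]
    rank_idx = [ranked[i].index(c) for i, c in enumerate(codons)]
    search_set = constraints.search_set
    substitutions = list(result.substitutions_for_motifs)

    while True:
        dna = "".join(codons)
        hits = find_motif_occurrences(dna, search_set)
        if not hits:
            break
        start, motif = hits[0]
        end = start + len(motif)
        overlapping = range(start // 3, (end - 1) // 3 + 1)
        accepted = False
        for ci in overlapping:
            for nxt in range(rank_idx[ci] + 1, len(ranked[ci])):
                candidate = ranked[ci][nxt]
                trial = codons.copy()
                trial[ci] = candidate
                if len(find_motif_occurrences("".join(trial), search_set)) < len(hits):
                    codons = trial
                    rank_idx[ci] = nxt
                    substitutions.append(ci + 1)
                    logger.info(
                        "motif %s at nt %d removed by %s->%s at codon %d",
                        motif, start + 1, result.output_seq.codons[ci],
                        candidate, ci + 1,
                    )
                    accepted = True
                    break
            if accepted:
                break
        if not accepted:
            raise MotifUnavoidableError(
                f"motif {motif} at nucleotide {start + 1} cannot be removed: "
                "no synonymous alternative at any overlapping codon "
                "eliminates it"
            )
    return _finalize(result.input_seq, codons, native, expr, substitutions)
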