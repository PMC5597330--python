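"""FASTA and TSV readers/writers plus the validated coding-sequence type.

FASTA goes through Biopython's SeqIO (gzip-transparent on read). Codon
tables use a small TSV dialect, one row per codon::

    # host_label=Escherichia coli K-12
    # n_cds=4242
    # n_codons=1356010
    # pseudo_rule=zero
    # table_id=1
    codon	amino_acid	count	fraction_in_family	rca
    AAA	K	45234	0.7421	1.0
    ...

The 64 data rows are alphabetical; counts are exact integers and RCA is
recomputed from them on read, so write -> read round-trips losslessly.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    ALL_CODONS,
    GeneticCode,
    SequenceError,
    STANDARD_CODE,
    codons_of,
    normalize_dna,
)
from .usage_tables import CodonUsageTable, counts_to_rca

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ("codon", "amino_acid", "count", "fraction_in_family", "rca")


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame DNA coding sequence.

    Construction normalizes case and U->T, then requires a length
    divisible by 3 over the ACGT alphabet.
    """

    label: str
    dna: str
    source_file: str = ""

    def __post_init__(self) -> None:
        dna = normalize_dna(self.dna)
        object.__setattr__(self, "dna", dna)
        if len(dna) == 0 or len(dna) % 3 != 0:
            raise SequenceError(
                f"{self.label or 'sequence'}: length {len(dna)} "
                "is not a positive multiple of 3"
            )
        bad = next((i for i, ch in enumerate(dna) if ch not in "ACGT"), None)
        if bad is not None:
            raise SequenceError(
                f"{self.label or 'sequence'}: non-ACGT character "
                f"{dna[bad]!r} at position {bad + 1}"
            )

    @property
    def codons(self) -> list[str]:
        return codons_of(self.dna)

    def translate(self, code: GeneticCode = STANDARD_CODE) -> str:
        return code.translate(self.dna)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA (optionally gzipped) into ``(label, sequence)`` pairs.

    Order is preserved; sequences are upper-cased with U mapped to T.
    Duplicate headers draw a warning; an empty file is an error.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        records = [(r.description, normalize_dna(str(r.seq))) for r in SeqIO.parse(handle, "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    for label, _ in records:
        if label in seen:
            logger.warning("%s: duplicate FASTA header %r", path, label)
        seen.add(label)
    return records


def read_coding_sequences(path: str | Path) -> list[CodingSequence]:
    """Read FASTA records as validated :class:`CodingSequence` objects."""
    return [
        CodingSequence(label=label, dna=dna, source_file=str(path))
        for label, dna in read_fasta(path)
    ]


def write_fasta(
    records: Iterable[CodingSequence | tuple[str, str]],
    path: str | Path,
    width: int = 70,
) -> None:
    seq_records = []
    for rec in records:
        label, dna = (rec.label, rec.dna) if isinstance(rec, CodingSequence) else rec
        seq_records.append(SeqRecord(Seq(dna), id=label.split()[0] if label else "seq",
                                     description=label))
    # SeqIO prepends id to description; write manually to keep headers verbatim
    with open(path, "w") as fh:
        for rec in seq_records:
            fh.write(f">{rec.description}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_codon_table(table: CodonUsageTable, path: str | Path) -> None:
    """Write the TSV dialect described in the module docstring."""
    if not table.rca:
        table = counts_to_rca(table)
    lines = [
        f"# host_label={table.host_label}",
        f"# n_cds={table.n_cds}",
        f"# n_codons={table.n_codons}",
        f"# pseudo_rule={table.pseudo_rule}",
        f"# table_id={table.code.table_id}",
        "\t".join(TABLE_COLUMNS),
    ]
    for codon in ALL_CODONS:
        aa = table.code.amino_acid(codon)
        lines.append(
            "\t".join(
                (
                    codon,
                    aa,
                    str(table.counts.get(codon, 0)),
                    format(table.family_fraction(codon), ".6f"),
                    repr(table.rca[codon]),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_codon_table(path: str | Path) -> CodonUsageTable:
    """Read a codon-table TSV; RCA is recomputed from the exact counts."""
    path = Path(path)
    meta: dict[str, str] = {}
    counts: dict[str, int] = {}
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != TABLE_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected columns {TABLE_COLUMNS}, got {fields}"
                )
            header_seen = True
            continue
        if len(fields) != len(TABLE_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(TABLE_COLUMNS)} columns")
        codon = normalize_dna(fields[0])
        if codon not in ALL_CODONS:
            raise ValueError(f"{path}:{lineno}: invalid codon {fields[0]!r}")
        counts[codon] = int(fields[2])
    missing = sorted(set(ALL_CODONS) - set(counts))
    if missing:
        raise ValueError(f"{path}: table is missing codon rows {missing[:4]}...")
    code = GeneticCode.from_table_id(int(meta.get("table_id", "1")))
    pseudo_rule = meta.get("pseudo_rule", "zero")
    if pseudo_rule not in ("zero", "sharp_half"):
        raise ValueError(f"{path}: unknown pseudo_rule {pseudo_rule!r}")
    table = CodonUsageTable(
        host_label=meta.get("host_label", ""),
        counts=counts,
        n_cds=int(meta.get("n_cds", "0")),
        n_codons=int(meta.get("n_codons", str(sum(counts.values())))),
        pseudo_rule=pseudo_rule,  # type: ignore[arg-type]
        code=code,
    )
    return counts_to_rca(table)


def write_report(rows: Sequence[dict], path: str | Path) -> None:
    """Write a list of uniform dicts as a plain TSV with a header row."""
    rows = list(rows)
    if not rows:
        raise ValueError("empty report")
    columns = list(rows[0])
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(_fmt(row[c]) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(value) -> str:
    if isinstance(value, float):
        return format(value, ".6f")
    return str(value)
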