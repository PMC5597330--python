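"""Score published gene-variant panels against locally supplied genomes.

Reproducing published CHI/CAI values for a panel of wild-type,
harmonized and optimized gene variants needs two kinds of input that
are never bundled with this package: the complete CDS FASTA of each
host genome (native hosts plus the expression host) and the variant
sequences themselves. Given those files locally, :func:`variant_report`
rebuilds the usage tables and scores every variant, optionally sweeping
the stop / single-codon-family inclusion conventions, since published
values may follow either convention and third-decimal agreement also
depends on the exact assembly and annotation version used for the
tables (which is why no assembly is hard-coded here).
"""

from __future__ import annotations

from pathlib import Path

from .io import CodingSequence, read_coding_sequences, read_fasta
from .metrics import cai, chi, profile
from .usage_tables import CodonUsageTable, build_table

#: The four stop / single-codon-family conventions worth sweeping.
FLAG_CONVENTIONS: tuple[dict[str, bool], ...] = (
    {"include_stop": True, "include_single_codon_aa": True},
    {"include_stop": False, "include_single_codon_aa": True},
    {"include_stop": True, "include_single_codon_aa": False},
    {"include_stop": False, "include_single_codon_aa": False},
)


def score_variant(
    variant: CodingSequence,
    wild_type: CodingSequence,
    native_table: CodonUsageTable,
    expr_table: CodonUsageTable,
    include_stop: bool = True,
    include_single_codon_aa: bool = True,
) -> dict[str, float]:
    """CAI of ``variant`` in the expression host and CHI against the
    wild-type's profile in the native host (positional pairing)."""
    flags = dict(
        include_stop=include_stop, include_single_codon_aa=include_single_codon_aa
    )
    p_expr = profile(variant, expr_table, **flags)
    p_native = profile(wild_type, native_table, **flags)
    return {"cai": cai(p_expr), "chi": chi(p_expr, p_native)}


def variant_report(
    wild_type: CodingSequence,
    variants: dict[str, CodingSequence],
    native_table: CodonUsageTable,
    expr_table: CodonUsageTable,
    sweep_flags: bool = False,
) -> dict:
    """Score a gene's variant panel; ``variants`` maps name -> sequence.

    With ``sweep_flags`` every convention in :data:`FLAG_CONVENTIONS`
    is reported, keyed ``stop=<bool>,single=<bool>``.
    """
    conventions = FLAG_CONVENTIONS if sweep_flags else FLAG_CONVENTIONS[:1]
    out: dict = {}
    for name, seq in variants.items():
        per_conv = {}
        for flags in conventions:
            key = f"stop={flags['include_stop']},single={flags['include_single_codon_aa']}"
            per_conv[key] = score_variant(
                seq, wild_type, native_table, expr_table, **flags
            )
        out[name] = per_conv if sweep_flags else next(iter(per_conv.values()))
    out["wild_type_native_cai"] = cai(profile(wild_type, native_table))
    return out


def reproduce_reference_scores(
    data_dir: str | Path, genes: dict[str, str], expr_cds: str = "expression_host_cds.fasta",
    sweep_flags: bool = True,
) -> dict:
    """Score every gene panel under ``data_dir``.

    ``genes`` maps a gene name to the file stem of its native host's
    CDS FASTA. Expected layout per gene ``G``::

        <data_dir>/<native_stem>_cds.fasta     all CDS of the native host
        <data_dir>/<G>_wild_type.fasta         wild-type gene
        <data_dir>/<G>_harmonized.fasta        harmonized variant
        <data_dir>/<G>_optimized.fasta         optimized variant
        <data_dir>/expression_host_cds.fasta   all CDS of the expression host

    Raises ``FileNotFoundError`` listing every missing file; these
    inputs must be fetched by the user (genome CDS sets from assembly
    databases, variants from the relevant supplementary material).
    """
    data_dir = Path(data_dir)
    needed = {data_dir / expr_cds}
    for gene, stem in genes.items():
        needed.add(data_dir / f"{stem}_cds.fasta")
        for variant in ("wild_type", "harmonized", "optimized"):
            needed.add(data_dir / f"{gene}_{variant}.fasta")
    missing = sorted(str(p) for p in needed if not p.exists())
    if missing:
        raise FileNotFoundError(
            "cannot score published variant panels; missing inputs "
            "(genome CDS sets and variant sequences are not "
            "redistributable with this package): " + ", ".join(missing)
        )
    expr_table = build_table(read_fasta(data_dir / expr_cds), host_label="expression host")
    report: dict = {}
    for gene, stem in genes.items():
        native_table = build_table(
            read_fasta(data_dir / f"{stem}_cds.fasta"), host_label=stem
        )
        wt = read_coding_sequences(data_dir / f"{gene}_wild_type.fasta")[0]
        variants = {
            v: read_coding_sequences(data_dir / f"{gene}_{v}.fasta")[0]
            for v in ("wild_type", "harmonized", "optimized")
        }
        report[gene] = variant_report(
            wt, variants, native_table, expr_table, sweep_flags=sweep_flags
        )
    return report
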