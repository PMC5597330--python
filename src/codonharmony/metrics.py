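"""Gene-level codon-usage metrics: RCA profiles, CAI, CHI, landscapes.

A gene's profile is the ordered series of RCA values of its codons
under one host's usage table. Two summary statistics condense it:

* CAI, the geometric mean of the per-codon RCA values,
  ``CAI = (prod RCA_i)^(1/N)`` — near 1 when the gene uses mostly the
  host's preferred codons;
* CHI, the codon harmonization index,
  ``CHI = (1/N) * sum |RCA_i - RCA_i,native|`` — the mean absolute
  per-position difference between a variant's RCA series in the
  expression host and the wild-type's series in the native host. CHI
  near 0 means the variant reproduces the native codon landscape,
  frequent and rare codons alike; harmonization minimizes it.

The landscape view keeps the per-position series and smooths it with a
short centered moving average (window 5 by default), the standard way
to visualize clusters of rare codons along a gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CodingSequence
from .usage_tables import CodonUsageTable

logger = logging.getLogger(__name__)


@dataclass
class GeneProfile:
    """Per-codon RCA series of one gene under one host table.

    ``aa_series`` carries the amino acid of each scored codon so that
    CHI can verify the two profiles describe synonymous variants of the
    same protein.
    """

    gene_label: str
    rca_series: np.ndarray
    aa_series: str
    include_stop: bool = True
    include_single_codon_aa: bool = True

    @property
    def n(self) -> int:
        return len(self.rca_series)


@dataclass
class LandscapeProfile:
    """RCA series with 1-based positions and a centered moving average."""

    gene_label: str
    positions: np.ndarray
    codons: list[str]
    amino_acids: str
    rca_series: np.ndarray
    moving_avg: np.ndarray
    window: int


def profile(
    seq: CodingSequence,
    table: CodonUsageTable,
    include_stop: bool = True,
    include_single_codon_aa: bool = True,
) -> GeneProfile:
    """RCA series of ``seq`` under ``table``.

    Both printed formulas run over "the number of codons in the gene",
    so by default every codon is scored. Classical CAI practice drops
    stop codons and the single-codon families Met/Trp (their RCA is 1
    by construction); the flags reproduce that convention.
    """
    if not table.rca:
        raise ValueError("usage table has no RCA scores; run counts_to_rca first")
    code = table.code
    rcas: list[float] = []
    aas: list[str] = []
    for codon in seq.codons:
        aa = code.amino_acid(codon)
        if not include_stop and aa == "*":
            continue
        if not include_single_codon_aa and len(code.families[aa]) == 1:
            continue
        rcas.append(table.rca[codon])
        aas.append(aa)
    return GeneProfile(
        gene_label=seq.label,
        rca_series=np.asarray(rcas, dtype=float),
        aa_series="".join(aas),
        include_stop=include_stop,
        include_single_codon_aa=include_single_codon_aa,
    )


def cai(p: GeneProfile) -> float:
    """Codon adaptation index: geometric mean of the RCA series.

    Computed as exp of the mean log for numerical stability. Any zero
    entry (an unobserved codon under the ``zero`` pseudo-rule) makes
    the result exactly 0, with a hint logged.
    """
    if p.n == 0:
        raise ValueError(f"{p.gene_label}: cannot score an empty profile")
    series = p.rca_series
    if np.any(series == 0.0):
        logger.warning(
            "%s: RCA series contains zeros, CAI collapses to 0 "
            "(consider pseudo_rule='sharp_half')",
            p.gene_label,
        )
        return 0.0
    return float(np.exp(np.mean(np.log(series))))


def chi(p_expr: GeneProfile, p_native: GeneProfile) -> float:
    """Codon harmonization index between two positionally paired profiles.

    ``p_expr`` is a variant scored in the expression host, ``p_native``
    the wild-type scored in the native host; both must have been built
    with the same flags from synonymous sequences of one protein.
    """
    if p_expr.n != p_native.n:
        raise ValueError(
            f"profile lengths differ: {p_expr.gene_label} has n={p_expr.n}, "
            f"{p_native.gene_label} has n={p_native.n}"
        )
    if p_expr.aa_series != p_native.aa_series:
        diff = next(
            i for i, (a, b) in enumerate(zip(p_expr.aa_series, p_native.aa_series))
            if a != b
        )
        raise ValueError(
            f"profiles are not synonymous: residue {diff + 1} is "
            f"{p_expr.aa_series[diff]} vs {p_native.aa_series[diff]}"
        )
    return float(np.mean(np.abs(p_expr.rca_series - p_native.rca_series)))


def landscape(
    seq: CodingSequence,
    table: CodonUsageTable,
    window: int = 5,
) -> LandscapeProfile:
    """Per-position RCA series with a centered moving average.

    The window must be odd; at the sequence ends it is clipped to the
    available codons, so the smoothed line spans the full gene.
    All codons are included (a landscape is positional; dropping
    positions would shift the residue axis).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    p = profile(seq, table, include_stop=True, include_single_codon_aa=True)
    series = pd.Series(p.rca_series)
    moving = series.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return LandscapeProfile(
        gene_label=seq.label,
        positions=np.arange(1, p.n + 1),
        codons=seq.codons,
        amino_acids=p.aa_series,
        rca_series=p.rca_series,
        moving_avg=moving,
        window=window,
    )
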