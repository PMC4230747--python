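"""Bias summaries and filtering rules applied to per-exon alignment tables.

Aligner workflows (simulated-read alignments, parental-read alignments,
ambiguity scans) are external to this package; their per-exon summaries
arrive as a TSV with columns ``exon_id, sim_maternal, sim_paternal,
sim_both, parental_wrong_fraction, ambiguous_read_count``.  This module
turns those summaries into fixed bias estimates for the Poisson-Gamma model
and into the classic filtering flags (allele assignment error, genome
ambiguity, extreme AI).  Threshold comparisons are strict where the rules
are stated strictly: "greater than 5%" wrongly-assigned reads, "at least 1"
ambiguous read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import pandas as pd

from .datamodel import BinomialResult, DnaCounts, PosteriorResult
from .exceptions import TableFormatError, UntestableExonError, ValidationError

__all__ = [
    "ExonBiasSummary",
    "q_from_simulation",
    "q_from_dna",
    "flag_allele_assignment_error",
    "flag_ambiguous",
    "flag_extreme_ai",
    "read_bias_summaries",
    "write_q_table",
]


@dataclass(frozen=True)
class ExonBiasSummary:
    """Per-exon summary of simulated-read alignments and error scans.

    ``sim_maternal`` / ``sim_paternal`` / ``sim_both`` are the counts of
    simulated reads aligning best (and uniquely) to the maternal reference,
    to the paternal reference, or equally well to both.
    ``parental_wrong_fraction`` is the fraction of reads from a parental
    sample that aligned better to the wrong reference;
    ``ambiguous_read_count`` the number of ambiguously-mapping reads.
    """

    exon_id: str
    sim_maternal: int = 0
    sim_paternal: int = 0
    sim_both: int = 0
    parental_wrong_fraction: float = 0.0
    ambiguous_read_count: int = 0

    def __post_init__(self) -> None:
        if min(self.sim_maternal, self.sim_paternal, self.sim_both,
               self.ambiguous_read_count) < 0:
            raise ValidationError(f"exon {self.exon_id}: counts must be >= 0")
        if not (0.0 <= self.parental_wrong_fraction <= 1.0):
            raise ValidationError(
                f"exon {self.exon_id}: parental_wrong_fraction must lie in [0, 1]"
            )


def q_from_simulation(s: ExonBiasSummary) -> float | None:
    """Map-bias estimate from simulated-read alignments.

    q = paternal / (maternal + paternal) over allele-specific reads only
    (the 'both' category carries no allele information and is excluded).
    Returns None when no allele-specific reads exist; a q of exactly 0 or 1
    is returned as-is but is unusable for the PG fit, which requires
    q in (0, 1) -- callers should screen with ``0 < q < 1``.
    """
    denom = s.sim_maternal + s.sim_paternal
    if denom == 0:
        return None
    return s.sim_paternal / denom


def q_from_dna(dna: DnaCounts) -> float:
    """Bias estimate from DNA controls: pooled paternal read fraction."""
    if dna.total == 0:
        raise UntestableExonError(f"exon {dna.exon_id}: DNA controls carry no reads")
    return dna.paternal_fraction


def flag_allele_assignment_error(
    s: ExonBiasSummary, threshold: float = 0.05
) -> bool:
    """True iff strictly more than ``threshold`` of parental reads mis-assigned."""
    return s.parental_wrong_fraction > threshold


def flag_ambiguous(s: ExonBiasSummary) -> bool:
    """True iff at least one ambiguous read aligns to the exon."""
    return s.ambiguous_read_count >= 1


def flag_extreme_ai(
    result: Union[PosteriorResult, BinomialResult], cut: float = 0.95
) -> bool:
    """True iff the estimated paternal proportion exceeds ``cut`` in either tail."""
    if isinstance(result, BinomialResult):
        est = result.p_hat
    else:
        est = result.theta_mean
    return est > cut or est < 1.0 - cut


_SUMMARY_COLS = [
    "exon_id", "sim_maternal", "sim_paternal", "sim_both",
    "parental_wrong_fraction", "ambiguous_read_count",
]


def read_bias_summaries(path) -> list[ExonBiasSummary]:
    """Read a per-exon bias summary TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SUMMARY_COLS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    return [
        ExonBiasSummary(
            exon_id=str(r.exon_id),
            sim_maternal=int(r.sim_maternal),
            sim_paternal=int(r.sim_paternal),
            sim_both=int(r.sim_both),
            parental_wrong_fraction=float(r.parental_wrong_fraction),
            ambiguous_read_count=int(r.ambiguous_read_count),
        )
        for r in df.itertuples()
    ]


def write_q_table(summaries, path) -> None:
    """Write per-exon q = simulation estimates (columns exon_id, q, usable).

    ``usable`` marks exons whose q lies strictly inside (0, 1); exons with
    no allele-specific simulated reads get an empty q.
    """
    rows = []
    for s in summaries:
        q = q_from_simulation(s)
        usable = q is not None and 0.0 < q < 1.0
        rows.append((s.exon_id, "" if q is None else repr(q), usable))
    pd.DataFrame(rows, columns=["exon_id", "q", "usable"]).to_csv(
        path, sep="\t", index=False
    )
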