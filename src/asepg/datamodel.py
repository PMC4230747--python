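"""Domain types and delimited-text I/O for allele-specific read counts.

The unit of analysis is the *exonic region*: for each exon and biological
replicate we observe a maternal and a paternal allele-specific read count,
from RNA-seq (:class:`AlleleCounts`) and optionally from genomic DNA of the
same F1 heterozygote (:class:`DnaCounts`).  DNA controls contain both
alleles in exactly equal amounts, so any departure of their paternal read
fraction from 1/2 measures mapping/sequencing bias rather than expression.

All tables are tab-delimited with an explicit header.  Counts tables carry
the columns ``exon_id, replicate, maternal_count, paternal_count``; the
exon identifier is an opaque string (the models consume counts only, never
coordinates).  Replicates are identified by an integer column rather than
file order, so RNA and DNA replicate numbers (I and I*) may differ.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    TableFormatError,
    UntestableExonError,
    ValidationError,
)

__all__ = [
    "AlleleCounts",
    "DnaCounts",
    "BiasMode",
    "BiasSpec",
    "PosteriorResult",
    "BinomialResult",
    "read_counts_table",
    "write_counts_table",
    "read_q_table",
    "write_results",
    "read_results",
]

COUNT_COLUMNS = ["exon_id", "replicate", "maternal_count", "paternal_count"]


def _as_count_array(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1 or arr.size < 1:
        raise ValidationError(f"{name} must be a non-empty 1-D sequence of counts")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValidationError(f"{name} must contain integers, got dtype {arr.dtype}")
    if np.any(arr < 0):
        raise ValidationError(f"{name} must be non-negative")
    return arr.astype(np.int64)


@dataclass(frozen=True)
class AlleleCounts:
    """Per-exon allele-specific RNA read counts across I biological replicates.

    Attributes
    ----------
    exon_id : str
        Opaque exonic-region identifier.
    x : ndarray of int, shape (I,)
        Maternal allele-specific read counts, one per replicate.
    y : ndarray of int, shape (I,)
        Paternal allele-specific read counts, one per replicate.
    """

    exon_id: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _as_count_array(self.x, "x"))
        object.__setattr__(self, "y", _as_count_array(self.y, "y"))
        if self.x.shape != self.y.shape:
            raise ValidationError(
                f"exon {self.exon_id}: maternal and paternal replicate counts differ "
                f"({self.x.size} vs {self.y.size})"
            )

    @property
    def n_replicates(self) -> int:
        return int(self.x.size)

    @property
    def total(self) -> int:
        """Total reads pooled over alleles and replicates."""
        return int(self.x.sum() + self.y.sum())

    @property
    def paternal_fraction(self) -> float:
        """Pooled observed paternal fraction; raises if the exon has no reads."""
        if self.total == 0:
            raise UntestableExonError(f"exon {self.exon_id} has no reads")
        return float(self.y.sum() / self.total)


@dataclass(frozen=True)
class DnaCounts:
    """Per-exon allele-specific DNA-control counts across I* replicates.

    Genomic DNA of the F1 carries both alleles in equal amounts, so these
    counts inform the bias parameter (p in the negative-binomial DNA model,
    the random bias phi in the Poisson-Gamma model) and never allelic
    imbalance itself.
    """

    exon_id: str
    x_star: np.ndarray
    y_star: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_star", _as_count_array(self.x_star, "x_star"))
        object.__setattr__(self, "y_star", _as_count_array(self.y_star, "y_star"))
        if self.x_star.shape != self.y_star.shape:
            raise ValidationError(
                f"exon {self.exon_id}: maternal and paternal DNA replicate counts differ"
            )

    @property
    def n_replicates(self) -> int:
        return int(self.x_star.size)

    @property
    def total(self) -> int:
        return int(self.x_star.sum() + self.y_star.sum())

    @property
    def paternal_fraction(self) -> float:
        if self.total == 0:
            raise UntestableExonError(f"exon {self.exon_id} has no DNA reads")
        return float(self.y_star.sum() / self.total)


class BiasMode(enum.Enum):
    """How mapping bias enters the Poisson-Gamma model."""

    FIXED_Q = "fixed_q"
    RANDOM_PHI = "random_phi"


@dataclass(frozen=True)
class BiasSpec:
    """Bias specification for the Poisson-Gamma model.

    ``FIXED_Q`` carries a known constant ``q`` in (0,1) -- q = 1/2 (no-bias
    assumption), q from simulated-read alignments, or q from pooled DNA
    controls.  ``RANDOM_PHI`` carries the DNA-control counts whose posterior
    supplies random bias draws.
    """

    mode: BiasMode
    q: float | None = None
    dna: DnaCounts | None = None

    def __post_init__(self) -> None:
        if self.mode is BiasMode.FIXED_Q:
            if self.q is None or not (0.0 < float(self.q) < 1.0):
                raise DomainError(f"FIXED_Q requires 0 < q < 1, got {self.q}")
        elif self.mode is BiasMode.RANDOM_PHI:
            if self.dna is None:
                raise DomainError("RANDOM_PHI requires DNA-control counts")
            if self.dna.total == 0:
                raise DomainError("RANDOM_PHI requires DNA controls with reads")

    @classmethod
    def fixed(cls, q: float) -> "BiasSpec":
        return cls(BiasMode.FIXED_Q, q=float(q))

    @classmethod
    def from_dna(cls, dna: DnaCounts) -> "BiasSpec":
        return cls(BiasMode.RANDOM_PHI, dna=dna)


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior summary for one exon from a Bayesian AI model.

    ``alpha`` is the treatment effect (alpha = 1 means allelic balance);
    ``theta = alpha/(1+alpha)`` is the bias-corrected paternal proportion.
    The AI decision is "the equal-tailed credible interval for alpha
    excludes 1", equivalently "the interval for theta excludes 1/2".
    """

    exon_id: str
    method: str
    alpha_draws: np.ndarray
    ci_level: float
    n_draws: int
    n_burnin: int
    seed: int
    mu_mean: float = math.nan
    beta_means: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        draws = np.asarray(self.alpha_draws, dtype=float)
        if draws.ndim != 1 or draws.size < 1:
            raise ValidationError("alpha_draws must be a non-empty 1-D array")
        if np.any(draws <= 0):
            raise ValidationError("alpha draws must be strictly positive")
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError("ci_level must lie in (0, 1)")
        object.__setattr__(self, "alpha_draws", draws)

    @property
    def theta_draws(self) -> np.ndarray:
        return self.alpha_draws / (1.0 + self.alpha_draws)

    @property
    def alpha_mean(self) -> float:
        return float(self.alpha_draws.mean())

    @property
    def theta_mean(self) -> float:
        return float(self.theta_draws.mean())

    @property
    def ci_alpha(self) -> tuple[float, float]:
        a = (1.0 - self.ci_level) / 2.0
        lo, hi = np.quantile(self.alpha_draws, [a, 1.0 - a])
        return float(lo), float(hi)

    @property
    def ci_theta(self) -> tuple[float, float]:
        lo, hi = self.ci_alpha
        return lo / (1.0 + lo), hi / (1.0 + hi)

    @property
    def ai_flag(self) -> bool:
        lo, hi = self.ci_alpha
        return not (lo <= 1.0 <= hi)


@dataclass(frozen=True)
class BinomialResult:
    """Result of a binomial test of allelic balance on pooled counts."""

    exon_id: str
    n: int
    p_hat: float
    z: float
    p_value: float
    ai_flag: bool
    variant: str  # "z" or "exact"
    level: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("binomial result requires n > 0")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_counts_table(path, kind: str = "RNA") -> list:
    """Read a tab-delimited allele-specific counts table.

    Parameters
    ----------
    path : path-like
        TSV file with header columns ``exon_id, replicate, maternal_count,
        paternal_count``.
    kind : {"RNA", "DNA"}
        ``"RNA"`` returns :class:`AlleleCounts`, ``"DNA"`` returns
        :class:`DnaCounts`.

    Returns
    -------
    list of AlleleCounts or DnaCounts, one per exon, replicates sorted by
    replicate index (input row order is irrelevant).  Exons appear in order
    of first appearance in the file.
    """
    kind = kind.upper()
    if kind not in ("RNA", "DNA"):
        raise ValueError(f"kind must be 'RNA' or 'DNA', got {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return []

    for col in ("replicate", "maternal_count", "paternal_count"):
        for row_idx, raw in zip(df.index, df[col]):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: row {row_idx + 2}: column {col!r} value {raw!r} "
                    "is not an integer"
                ) from None
            if val < 0:
                raise ValidationError(
                    f"{path}: row {row_idx + 2}: column {col!r} is negative ({val})"
                )
    df = df.assign(
        replicate=df["replicate"].astype(int),
        maternal_count=df["maternal_count"].astype(int),
        paternal_count=df["paternal_count"].astype(int),
    )
    dup = df.duplicated(subset=["exon_id", "replicate"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (exon_id, replicate) = "
            f"({first['exon_id']!r}, {first['replicate']})"
        )

    records = []
    for exon_id, grp in df.groupby("exon_id", sort=False):
        grp = grp.sort_values("replicate")
        m = grp["maternal_count"].to_numpy()
        p = grp["paternal_count"].to_numpy()
        if kind == "RNA":
            records.append(AlleleCounts(exon_id=str(exon_id), x=m, y=p))
        else:
            records.append(DnaCounts(exon_id=str(exon_id), x_star=m, y_star=p))
    return records


def write_counts_table(records: Iterable[Union[AlleleCounts, DnaCounts]], path) -> None:
    """Write counts back to the canonical TSV layout (inverse of read)."""
    rows = []
    for rec in records:
        if isinstance(rec, AlleleCounts):
            m, p = rec.x, rec.y
        else:
            m, p = rec.x_star, rec.y_star
        for i, (mi, pi) in enumerate(zip(m, p), start=1):
            rows.append((rec.exon_id, i, int(mi), int(pi)))
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_q_table(path) -> dict[str, float]:
    """Read a per-exon fixed-bias table (columns ``exon_id, q``)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("exon_id", "q"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column(s) ['{col}']")
    return {str(e): float(q) for e, q in zip(df["exon_id"], df["q"])}


_POSTERIOR_COLS = [
    "exon_id", "method", "theta_hat", "theta_lo", "theta_hi",
    "alpha_hat", "alpha_lo", "alpha_hi", "ai_flag",
]
_BINOMIAL_COLS = ["exon_id", "method", "n", "p_hat", "z", "p_value", "ai_flag"]


def write_results(results: Sequence[Union[PosteriorResult, BinomialResult]], path) -> None:
    """Write per-exon results as TSV at full float precision.

    Bayesian rows carry the theta/alpha point estimates and CI bounds;
    binomial rows carry n, p-hat, z and the p-value.  A single file holds
    one kind of row; mixing kinds raises :class:`ValidationError`.
    """
    results = list(results)
    kinds = {isinstance(r, BinomialResult) for r in results}
    if len(kinds) > 1:
        raise ValidationError("cannot mix Bayesian and binomial results in one table")
    if results and isinstance(results[0], BinomialResult):
        rows = [
            (r.exon_id, f"binomial_{r.variant}", r.n, repr(r.p_hat), repr(r.z),
             repr(r.p_value), r.ai_flag)
            for r in results
        ]
        pd.DataFrame(rows, columns=_BINOMIAL_COLS).to_csv(path, sep="\t", index=False)
    else:
        rows = []
        for r in results:
            alo, ahi = r.ci_alpha
            tlo, thi = r.ci_theta
            rows.append(
                (r.exon_id, r.method, repr(r.theta_mean), repr(tlo), repr(thi),
                 repr(r.alpha_mean), repr(alo), repr(ahi), r.ai_flag)
            )
        pd.DataFrame(rows, columns=_POSTERIOR_COLS).to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (flags as booleans)."""
    df = pd.read_csv(path, sep="\t")
    if "ai_flag" in df.columns:
        df["ai_flag"] = df["ai_flag"].astype(bool)
    return df
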