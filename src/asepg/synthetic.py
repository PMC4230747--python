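"""Poisson simulator for allele-specific RNA and DNA-control read counts.

Each exonic region gets a baseline per-allele mean ``lambda`` drawn once
from a coverage distribution; RNA counts are then

    x_i  ~ Poisson(2 * lambda * (1 - B))        (maternal)
    y_i  ~ Poisson(2 * lambda * B * R)          (paternal)

independently over replicates, and DNA-control counts use the same means
with ``R = 1`` (genomic DNA carries both alleles equally, so it shows bias
but never allelic imbalance):

    x*_i ~ Poisson(2 * lambda * (1 - B)),  y*_i ~ Poisson(2 * lambda * B).

``B`` in (0,1) is the bias -- at ``R = 1`` the expected paternal read
fraction is exactly ``B`` -- and ``R > 0`` is the allelic ratio: the
paternal:maternal ratio of allele mean counts, so ``R = 1`` is the null of
no allelic imbalance.  The same ``lambda`` is shared between RNA and DNA
for an exon (the control measures the same region); an independent-lambda
mode exists for robustness checks.

Every exon uses an independent RNG sub-stream keyed by (seed, exon index),
so the simulation is fully reproducible and changing ``n_exons`` never
perturbs earlier exons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AlleleCounts, DnaCounts
from .exceptions import DomainError

__all__ = [
    "Coverage",
    "SimConfig",
    "SimData",
    "simulate_arrays",
    "simulate_counts",
    "misspecified_q",
    "bias_grid",
]


@dataclass(frozen=True)
class Coverage:
    """Distribution of the per-exon baseline per-allele mean count lambda.

    Families: ``fixed:lam``; ``lognormal:median:log_sd``;
    ``gamma:shape:mean``.  The default (lognormal, median 150, log-sd 0.8)
    emulates the skewed exon-level depth of a typical bulk RNA-seq library.
    """

    family: str = "lognormal"
    params: tuple[float, ...] = (150.0, 0.8)

    def __post_init__(self) -> None:
        fam = self.family
        p = self.params
        if fam == "fixed":
            if len(p) != 1 or p[0] <= 0:
                raise DomainError("fixed coverage needs one positive parameter (lam)")
        elif fam == "lognormal":
            if len(p) != 2 or p[0] <= 0 or p[1] < 0:
                raise DomainError(
                    "lognormal coverage needs (median > 0, log_sd >= 0)"
                )
        elif fam == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise DomainError("gamma coverage needs (shape > 0, mean > 0)")
        else:
            raise DomainError(f"unknown coverage family {fam!r}")

    @classmethod
    def parse(cls, text: str) -> "Coverage":
        """Parse a ``family:param1[:param2]`` string, e.g. ``lognormal:150:0.8``."""
        parts = text.split(":")
        try:
            return cls(parts[0], tuple(float(v) for v in parts[1:]))
        except ValueError as exc:
            raise DomainError(f"cannot parse coverage spec {text!r}") from exc

    @classmethod
    def fixed(cls, lam: float) -> "Coverage":
        return cls("fixed", (float(lam),))

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.params[0]
        if self.family == "lognormal":
            median, log_sd = self.params
            return float(median * np.exp(log_sd * rng.standard_normal()))
        shape, mean = self.params
        return float(rng.gamma(shape) * (mean / shape))


DEFAULT_COVERAGE = Coverage()


@dataclass(frozen=True)
class SimConfig:
    """Generative contract of one simulated data set."""

    n_exons: int
    I: int = 3
    I_star: int = 3
    B: float = 0.5
    R: float = 1.0
    coverage: Coverage = field(default_factory=Coverage)
    seed: int = 0
    shared_lambda: bool = True

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise DomainError("n_exons must be >= 1")
        if self.I < 1 or self.I_star < 1:
            raise DomainError("replicate counts must be >= 1")
        if not (0.0 < self.B < 1.0):
            raise DomainError(f"B must lie in (0, 1), got {self.B}")
        if self.R <= 0:
            raise DomainError(f"R must be > 0, got {self.R}")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SimData:
    """Array view of one simulated data set (exons along axis 0)."""

    exon_ids: np.ndarray            # (n,) strings
    x: np.ndarray                   # (n, I) maternal RNA
    y: np.ndarray                   # (n, I) paternal RNA
    x_star: np.ndarray              # (n, I*) maternal DNA
    y_star: np.ndarray              # (n, I*) paternal DNA
    lam: np.ndarray                 # (n,) baseline means (RNA)
    config: SimConfig


def simulate_arrays(config: SimConfig) -> SimData:
    """Simulate counts for all exons, returning stacked arrays."""
    n = config.n_exons
    x = np.empty((n, config.I), dtype=np.int64)
    y = np.empty_like(x)
    xs = np.empty((n, config.I_star), dtype=np.int64)
    ys = np.empty_like(xs)
    lam = np.empty(n)
    B, R = config.B, config.R
    for e in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, e]))
        lam_e = config.coverage.sample(rng)
        lam[e] = lam_e
        x[e] = rng.poisson(2.0 * lam_e * (1.0 - B), size=config.I)
        y[e] = rng.poisson(2.0 * lam_e * B * R, size=config.I)
        lam_dna = lam_e if config.shared_lambda else config.coverage.sample(rng)
        xs[e] = rng.poisson(2.0 * lam_dna * (1.0 - B), size=config.I_star)
        ys[e] = rng.poisson(2.0 * lam_dna * B, size=config.I_star)
    width = max(5, len(str(n)))
    ids = np.array([f"exon_{e:0{width}d}" for e in range(n)])
    return SimData(exon_ids=ids, x=x, y=y, x_star=xs, y_star=ys, lam=lam,
                   config=config)


def simulate_counts(
    config: SimConfig,
) -> tuple[list[AlleleCounts], list[DnaCounts], pd.DataFrame]:
    """Simulate counts as domain records plus a per-exon truth table.

    Returns (RNA records, DNA records, truth), where truth has one row per
    exon with its exon_id, lambda, B and R.
    """
    data = simulate_arrays(config)
    rna = [
        AlleleCounts(exon_id=eid, x=xi, y=yi)
        for eid, xi, yi in zip(data.exon_ids, data.x, data.y)
    ]
    dna = [
        DnaCounts(exon_id=eid, x_star=xi, y_star=yi)
        for eid, xi, yi in zip(data.exon_ids, data.x_star, data.y_star)
    ]
    truth = pd.DataFrame(
        {
            "exon_id": data.exon_ids,
            "lambda": data.lam,
            "B": config.B,
            "R": config.R,
        }
    )
    return rna, dna, truth


def misspecified_q(B: float, pct: float) -> float:
    """Bias constant misspecified by ``pct`` percent: q = (1 + pct/100) * B."""
    q = (1.0 + pct / 100.0) * B
    if not (0.0 < q < 1.0):
        raise DomainError(
            f"misspecified q = (1 + {pct}%)*{B} = {q:.4f} falls outside (0, 1)"
        )
    return q


def bias_grid(x_pct) -> np.ndarray:
    """Map a bias-sweep axis (percent above 0.5) to B values: B = 0.5(1 + x/100)."""
    x = np.asarray(x_pct, dtype=float)
    B = 0.5 * (1.0 + x / 100.0)
    if np.any((B <= 0.0) | (B >= 1.0)):
        raise DomainError("bias grid maps outside (0, 1)")
    return B
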