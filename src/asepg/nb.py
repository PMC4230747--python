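"""The Negative Binomial (NB) model of allelic imbalance with DNA controls.

Treats the read totals as random rather than fixed.  With the NB
parameterized so that ``eta ~ NegativeBinomial(k, eps)`` counts the number
of failures before the first ``k`` successes (success probability ``eps``):

DNA model (bias):   y*_i | p   ~ NB(k = x*_i, eps = 1 - p),  i = 1..I*
RNA model (AI):     y_i  | th  ~ NB(k = x_i,  eps = 1 - th), i = 1..I

``p`` is the paternal proportion in the DNA control (pure bias, since the
control carries both alleles equally) and ``theta`` the paternal proportion
observed in RNA.  The DNA information enters the RNA model through the
prior ``theta | p ~ Beta(kappa * p, kappa * (1 - p))``, i.e. a prior
centred at the measured bias and worth ``kappa`` pseudo-reads; by default
``kappa`` equals the total DNA read count, so the prior carries exactly
the DNA evidence.

The imbalance parameter is the bias-corrected odds ratio

    alpha = [theta / (1 - theta)] / [p0 / (1 - p0)],

where ``p0`` is the DNA posterior median -- the null expectation for theta
when expression is balanced but assignment is biased.  This mirrors the
Poisson-Gamma decomposition (observed paternal odds = alpha times bias
odds): allelic imbalance is flagged when the credible interval for alpha
excludes 1, equivalently when the interval for theta excludes the
DNA-implied null ``p0``.  When the DNA is balanced, ``p0 = 1/2`` and the
rule reduces to "theta interval excludes 1/2".

Both stages are conjugate: the NB likelihood in ``p`` (or ``theta``) is
proportional to ``p^{sum y} (1-p)^{sum x}``, so the DNA posterior is
``Beta(a + sum y*, b + sum x*)`` and, given ``p``, the RNA posterior is
``Beta(kappa p + sum y, kappa(1-p) + sum x)``.  Inference is two-stage
(cut): bias draws from the DNA posterior are treated as fixed truth inside
the RNA model.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import AlleleCounts, DnaCounts, PosteriorResult
from .exceptions import DomainError, UntestableExonError

__all__ = ["NBModelSpec", "p_posterior_params", "posterior_p_draws", "fit_nb"]


@dataclass(frozen=True)
class NBModelSpec:
    """Priors and sampler settings for the NB model.

    ``prior_a``/``prior_b`` give the Beta prior on the DNA bias proportion
    p (Jeffreys Beta(1/2, 1/2) by default).  ``kappa`` is the concentration
    of the p-centred Beta prior on theta; ``None`` means "use the total DNA
    read count of the exon being fitted".
    """

    prior_a: float = 0.5
    prior_b: float = 0.5
    kappa: float | None = None
    ci_level: float = 0.95
    n_draws: int = 10_000
    n_burnin: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise DomainError("Beta prior parameters must be > 0")
        if self.kappa is not None and self.kappa <= 0:
            raise DomainError("kappa must be > 0")
        if not (0.0 < self.ci_level < 1.0):
            raise DomainError("ci_level must lie in (0, 1)")
        if self.n_draws < 1 or self.n_burnin < 0:
            raise DomainError("n_draws >= 1 and n_burnin >= 0 required")

    def replace(self, **kw) -> "NBModelSpec":
        return dataclasses.replace(self, **kw)


def _usable_sums(x: np.ndarray, y: np.ndarray, label: str) -> tuple[int, int]:
    """Pool replicate counts, dropping replicates the NB cannot express.

    A replicate with zero successes (maternal count 0) but nonzero failures
    has zero likelihood under NB(k=0, .); such replicates are dropped with a
    warning rather than silently imputed.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    bad = (x == 0) & (y > 0)
    if bad.any():
        warnings.warn(
            f"{label}: dropping {int(bad.sum())} replicate(s) with zero maternal "
            "count but nonzero paternal count (undefined under the NB likelihood)",
            stacklevel=3,
        )
    keep = ~bad
    return int(x[keep].sum()), int(y[keep].sum())


def p_posterior_params(
    dna: DnaCounts, prior_a: float = 0.5, prior_b: float = 0.5
) -> tuple[float, float]:
    """Beta posterior parameters (a, b) of the DNA-model bias proportion p.

    The NB likelihood over replicates is proportional to
    ``p^{sum y*} (1-p)^{sum x*}``, so with ``p ~ Beta(a0, b0)`` the
    posterior is ``Beta(a0 + sum y*, b0 + sum x*)`` exactly.
    """
    if dna.total == 0:
        raise UntestableExonError(f"exon {dna.exon_id}: DNA controls carry no reads")
    xs, ys = _usable_sums(dna.x_star, dna.y_star, f"exon {dna.exon_id} (DNA)")
    if xs + ys == 0:
        raise UntestableExonError(
            f"exon {dna.exon_id}: no usable DNA replicates after dropping "
            "zero-maternal replicates"
        )
    return prior_a + ys, prior_b + xs


def posterior_p_draws(dna: DnaCounts, spec: NBModelSpec | None = None) -> np.ndarray:
    """Draws of the bias proportion p from the DNA-model posterior."""
    spec = spec or NBModelSpec()
    a, b = p_posterior_params(dna, spec.prior_a, spec.prior_b)
    rng = np.random.default_rng(spec.seed)
    return rng.beta(a, b, size=spec.n_draws)


def fit_nb(
    counts: AlleleCounts, dna: DnaCounts, spec: NBModelSpec | None = None
) -> PosteriorResult:
    """Fit the NB model for one exon with DNA controls.

    Two-stage sampling for each iteration m: draw ``p^m`` from the DNA
    posterior, then ``theta^m ~ Beta(kappa p^m + sum y, kappa(1-p^m) +
    sum x)``.  The result is reported on the bias-corrected treatment
    scale ``alpha = odds(theta) / odds(p0)`` (``p0`` the DNA posterior
    median), uniform with the PG model, so the generic decision rule
    "alpha interval excludes 1" tests theta against the DNA-implied null.
    """
    spec = spec or NBModelSpec()
    if counts.total == 0:
        raise UntestableExonError(f"exon {counts.exon_id}: no RNA reads; NB fit undefined")
    a_p, b_p = p_posterior_params(dna, spec.prior_a, spec.prior_b)
    x_sum, y_sum = _usable_sums(counts.x, counts.y, f"exon {counts.exon_id} (RNA)")
    if x_sum + y_sum == 0:
        raise UntestableExonError(
            f"exon {counts.exon_id}: no usable RNA replicates under the NB likelihood"
        )
    kappa = spec.kappa if spec.kappa is not None else float(dna.total)

    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_burnin + spec.n_draws
    p = rng.beta(a_p, b_p, size=n_total)
    theta = rng.beta(kappa * p + y_sum, kappa * (1.0 - p) + x_sum)
    theta = theta[spec.n_burnin:]
    theta = np.clip(theta, 1e-12, 1.0 - 1e-12)
    p0 = stats.beta.ppf(0.5, a_p, b_p)        # DNA-implied null for theta
    alpha = (theta / (1.0 - theta)) * ((1.0 - p0) / p0)
    return PosteriorResult(
        exon_id=counts.exon_id,
        method="nb_dna",
        alpha_draws=alpha,
        ci_level=spec.ci_level,
        n_draws=spec.n_draws,
        n_burnin=spec.n_burnin,
        seed=spec.seed,
    )
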