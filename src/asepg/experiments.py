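"""Monte-Carlo drivers: type I error, power, bias sweeps, misspecification.

These drivers simulate many exonic regions under a known bias ``B`` and
allelic ratio ``R``, run one of the tests/models on every exon, and report
the fraction of exons flagged as in allelic imbalance.  At ``R = 1``
(no AI) that fraction is the empirical type I error rate (TIER); at
``R != 1`` it is power.  Decisions are per exon at the 5% level (credible
level 0.95) with no multiplicity correction, since type I error is defined
per test.

Methods
-------
``binomial_exact`` / ``binomial_z``
    Pooled binomial tests assuming no bias.
``pg_fixed_q``
    Poisson-Gamma with a fixed bias constant chosen by a :class:`QPolicy`:
    ``half`` (q = 1/2), ``true_b`` (q = B, the oracle bias) or
    ``misspec(pct)`` (q = (1 + pct/100) B).
``pg_phi_dna``
    Poisson-Gamma with random bias phi drawn from the DNA-control posterior.
``nb_dna``
    Negative-binomial model with the DNA-informed Beta prior on theta.

The Bayesian methods run a vectorized Gibbs/conjugate sampler over chunks
of exons, so the full 10,000-exon, 10,000-draw study completes in minutes
on one CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import binomial as _binomial
from . import pg as _pg
from . import synthetic as _synthetic
from .binomial import Z_CUTOFF
from .exceptions import ExperimentMisuseError, ValidationError
from .pg import PGModelSpec
from .synthetic import SimConfig, SimData

__all__ = [
    "METHODS",
    "QPolicy",
    "RateEstimate",
    "type1_error",
    "power",
    "bias_sweep",
    "misspec_surface",
    "concordance",
    "ConcordanceResult",
    "plot_bias_sweep",
    "plot_misspec_surface",
]

METHODS = ("binomial_exact", "binomial_z", "nb_dna", "pg_phi_dna", "pg_fixed_q")


@dataclass(frozen=True)
class QPolicy:
    """How the fixed bias constant q is chosen relative to the true bias B."""

    kind: str                     # "half" | "true_b" | "misspec"
    pct: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("half", "true_b", "misspec"):
            raise ExperimentMisuseError(f"unknown q policy {self.kind!r}")

    @classmethod
    def half(cls) -> "QPolicy":
        return cls("half")

    @classmethod
    def true_b(cls) -> "QPolicy":
        return cls("true_b")

    @classmethod
    def misspec(cls, pct: float) -> "QPolicy":
        return cls("misspec", pct=float(pct))

    def value(self, B: float) -> float:
        if self.kind == "half":
            return 0.5
        if self.kind == "true_b":
            return float(B)
        return _synthetic.misspecified_q(B, self.pct)

    def label(self) -> str:
        if self.kind == "misspec":
            return f"misspec[{self.pct:g}%]"
        return self.kind


@dataclass(frozen=True)
class RateEstimate:
    """An empirical rejection rate with its binomial Monte-Carlo SE."""

    method: str
    rate: float
    se: float
    n_exons: int
    flags: np.ndarray
    B: float
    R: float
    q_label: str = ""

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def _ci_flags_from_alpha(alpha_draws: np.ndarray, ci_level: float) -> np.ndarray:
    a = (1.0 - ci_level) / 2.0
    lo = np.quantile(alpha_draws, a, axis=1)
    hi = np.quantile(alpha_draws, 1.0 - a, axis=1)
    return (lo > 1.0) | (hi < 1.0)


def _binomial_flags(data: SimData, variant: str, level: float) -> np.ndarray:
    y_tot = data.y.sum(axis=1)
    n_tot = data.x.sum(axis=1) + y_tot
    ok = n_tot > 0
    flags = np.zeros(data.config.n_exons, dtype=bool)
    if variant == "z":
        p_hat = np.divide(y_tot, n_tot, out=np.full_like(n_tot, 0.5, dtype=float),
                          where=ok)
        z = (p_hat - 0.5) / np.sqrt(0.25 / np.maximum(n_tot, 1))
        flags[ok] = np.abs(z[ok]) > Z_CUTOFF
    else:
        p = _binomial.exact_pvalues_vectorized(y_tot[ok], n_tot[ok])
        flags[ok] = p < level
    return flags


def _pg_flags(
    data: SimData,
    spec: PGModelSpec,
    sampler_seed: int,
    *,
    q: float | None = None,
    random_phi: bool = False,
    chunk_size: int = 2500,
) -> np.ndarray:
    n = data.config.n_exons
    flags = np.empty(n, dtype=bool)
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        child = np.random.SeedSequence([int(sampler_seed), 91, start])
        kw = {}
        if random_phi:
            a_p = spec.phi_prior_a + data.y_star[sl].sum(axis=1)
            b_p = spec.phi_prior_b + data.x_star[sl].sum(axis=1)
            kw["phi_beta_params"] = (a_p.astype(float), b_p.astype(float))
        else:
            kw["q"] = np.full(sl.stop - sl.start, float(q))
        draws = _pg.symmetrized_alpha_draws(
            data.x[sl].astype(float), data.y[sl].astype(float), spec, child,
            out_dtype=np.float32, **kw,
        )
        flags[sl] = _ci_flags_from_alpha(draws, spec.ci_level)
    return flags


def _nb_flags(
    data: SimData,
    spec: PGModelSpec,
    rng: np.random.Generator,
    *,
    chunk_size: int = 2500,
) -> np.ndarray:
    """Vectorized NB fits: conjugate two-stage Beta sampling per exon.

    Replicates with zero maternal but nonzero paternal reads are excluded
    from the pooled sums (same rule as :func:`asepg.nb.fit_nb`); kappa is
    the per-exon total DNA read count.
    """
    bad_rna = (data.x == 0) & (data.y > 0)
    bad_dna = (data.x_star == 0) & (data.y_star > 0)
    x_sum = np.where(bad_rna, 0, data.x).sum(axis=1).astype(float)
    y_sum = np.where(bad_rna, 0, data.y).sum(axis=1).astype(float)
    xs_sum = np.where(bad_dna, 0, data.x_star).sum(axis=1).astype(float)
    ys_sum = np.where(bad_dna, 0, data.y_star).sum(axis=1).astype(float)
    kappa = data.x_star.sum(axis=1) + data.y_star.sum(axis=1)
    kappa = np.maximum(kappa, 1.0).astype(float)

    n = data.config.n_exons
    flags = np.empty(n, dtype=bool)
    a_lvl = (1.0 - spec.ci_level) / 2.0
    from scipy import stats as _stats

    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        m = spec.n_draws
        a_p = 0.5 + ys_sum[sl]
        b_p = 0.5 + xs_sum[sl]
        p = rng.beta(a_p[:, None], b_p[:, None], size=(a_p.size, m))
        k = kappa[sl][:, None]
        theta = rng.beta(k * p + y_sum[sl][:, None],
                         k * (1.0 - p) + x_sum[sl][:, None]).astype(np.float32)
        lo = np.quantile(theta, a_lvl, axis=1)
        hi = np.quantile(theta, 1.0 - a_lvl, axis=1)
        p0 = _stats.beta.ppf(0.5, a_p, b_p)   # DNA-implied null for theta
        flags[sl] = (lo > p0) | (hi < p0)
    return flags


def _run_method(
    method: str,
    data: SimData,
    q_policy: QPolicy | None,
    draws: int,
    burnin: int,
    ci_level: float,
    chunk_size: int,
    sampler_seed: int | None,
) -> tuple[np.ndarray, str]:
    if method not in METHODS:
        raise ExperimentMisuseError(f"unknown method {method!r}; one of {METHODS}")
    if q_policy is not None and method != "pg_fixed_q":
        raise ExperimentMisuseError("q_policy applies only to method 'pg_fixed_q'")
    level = 1.0 - ci_level
    if method == "binomial_exact":
        return _binomial_flags(data, "exact", level), ""
    if method == "binomial_z":
        return _binomial_flags(data, "z", level), ""
    if sampler_seed is None:
        sampler_seed = data.config.seed
    spec = PGModelSpec(ci_level=ci_level, n_draws=draws, n_burnin=burnin,
                       seed=sampler_seed)
    if method == "pg_fixed_q":
        if q_policy is None:
            raise ExperimentMisuseError("method 'pg_fixed_q' requires a q_policy")
        q = q_policy.value(data.config.B)
        return (
            _pg_flags(data, spec, sampler_seed, q=q, chunk_size=chunk_size),
            q_policy.label(),
        )
    if method == "pg_phi_dna":
        return _pg_flags(data, spec, sampler_seed, random_phi=True,
                         chunk_size=chunk_size), ""
    rng = np.random.default_rng(np.random.SeedSequence([sampler_seed, 10_007]))
    return _nb_flags(data, spec, rng, chunk_size=chunk_size), ""


def _rate(method, flags, config, q_label) -> RateEstimate:
    rate = float(flags.mean())
    se = float(np.sqrt(rate * (1.0 - rate) / flags.size))
    return RateEstimate(method=method, rate=rate, se=se, n_exons=flags.size,
                        flags=flags, B=config.B, R=config.R, q_label=q_label)


def type1_error(
    method: str,
    config: SimConfig,
    q_policy: QPolicy | None = None,
    *,
    draws: int = 10_000,
    burnin: int = 2_000,
    ci_level: float = 0.95,
    chunk_size: int = 2500,
    sampler_seed: int | None = None,
) -> RateEstimate:
    """Empirical type I error rate of ``method`` under a null simulation.

    Requires ``config.R == 1`` (every exon truly balanced); the returned
    rate is the fraction of exons falsely flagged as in AI.
    """
    if config.R != 1.0:
        raise ExperimentMisuseError(
            "type1_error requires R = 1 (null simulation); use power() for R != 1"
        )
    data = _synthetic.simulate_arrays(config)
    flags, q_label = _run_method(method, data, q_policy, draws, burnin,
                                 ci_level, chunk_size, sampler_seed)
    return _rate(method, flags, config, q_label)


def power(
    method: str,
    config: SimConfig,
    q_policy: QPolicy | None = None,
    *,
    draws: int = 10_000,
    burnin: int = 2_000,
    ci_level: float = 0.95,
    chunk_size: int = 2500,
    sampler_seed: int | None = None,
) -> RateEstimate:
    """Empirical power of ``method`` when every exon is truly imbalanced (R != 1)."""
    if config.R == 1.0:
        raise ExperimentMisuseError(
            "power requires R != 1 (imbalanced simulation); use type1_error for R = 1"
        )
    data = _synthetic.simulate_arrays(config)
    flags, q_label = _run_method(method, data, q_policy, draws, burnin,
                                 ci_level, chunk_size, sampler_seed)
    return _rate(method, flags, config, q_label)


def bias_sweep(
    x_grid: Sequence[float],
    methods: Sequence[str],
    config: SimConfig,
    q_policies: dict[str, QPolicy] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """TIER of each method along a bias axis ``B = 0.5 (1 + x/100)``.

    ``config`` supplies everything except B; the same simulation seed is
    reused at each grid point (common random numbers), which sharpens the
    between-method and between-bias comparisons the sweep exists for.
    Default q policy for ``pg_fixed_q`` is q = 1/2.
    """
    q_policies = q_policies or {}
    Bs = _synthetic.bias_grid(x_grid)
    rows = []
    for x, B in zip(x_grid, Bs):
        cfg = config.replace(B=float(B))
        for method in methods:
            pol = q_policies.get(method, QPolicy.half() if method == "pg_fixed_q" else None)
            est = type1_error(method, cfg, pol, **kwargs)
            rows.append(
                {"x_pct": x, "B": B, "method": method, "q_policy": est.q_label,
                 "tier": est.rate, "se": est.se, "n_exons": est.n_exons}
            )
    return pd.DataFrame(rows)


def misspec_surface(
    x_grid: Sequence[float],
    pct_grid: Sequence[float] = (0, 1, 2, 5, 10),
    config: SimConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """TIER of the PG model at q = (1 + pct/100) B over a (bias, pct) grid."""
    if config is None:
        raise ExperimentMisuseError("misspec_surface requires a SimConfig")
    Bs = _synthetic.bias_grid(x_grid)
    rows = []
    for x, B in zip(x_grid, Bs):
        cfg = config.replace(B=float(B))
        for pct in pct_grid:
            pol = QPolicy.true_b() if pct == 0 else QPolicy.misspec(pct)
            est = type1_error("pg_fixed_q", cfg, pol, **kwargs)
            rows.append(
                {"x_pct": x, "B": B, "pct": pct, "q": pol.value(B),
                 "tier": est.rate, "se": est.se, "n_exons": est.n_exons}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConcordanceResult:
    """2x2 cross-tabulation of AB/AI calls, with b treated as truth."""

    table: pd.DataFrame           # fractions, rows = a, cols = b
    sensitivity: float
    specificity: float
    false_positive_fraction: float
    n_exons: int


def concordance(results_a, results_b) -> ConcordanceResult:
    """Cross-tabulate the AI calls of two result sets on the same exons.

    Fractions sum to 1 over the four (AB, AI) x (AB, AI) cells.
    Sensitivity, specificity and the false-positive fraction treat
    ``results_b`` as truth (so FP fraction = 1 - specificity).
    """
    ids_a = [r.exon_id for r in results_a]
    ids_b = [r.exon_id for r in results_b]
    if ids_a != ids_b:
        raise ValidationError("concordance requires the same exons in the same order")
    if not ids_a:
        raise ValidationError("concordance requires at least one exon")
    fa = np.array([bool(r.ai_flag) for r in results_a])
    fb = np.array([bool(r.ai_flag) for r in results_b])
    n = fa.size
    cells = np.array(
        [
            [np.mean(~fa & ~fb), np.mean(~fa & fb)],
            [np.mean(fa & ~fb), np.mean(fa & fb)],
        ]
    )
    table = pd.DataFrame(cells, index=["a:AB", "a:AI"], columns=["b:AB", "b:AI"])
    n_pos = int(fb.sum())
    n_neg = n - n_pos
    sens = float((fa & fb).sum() / n_pos) if n_pos else float("nan")
    spec = float((~fa & ~fb).sum() / n_neg) if n_neg else float("nan")
    fp = 1.0 - spec if n_neg else float("nan")
    return ConcordanceResult(table=table, sensitivity=sens, specificity=spec,
                             false_positive_fraction=fp, n_exons=n)


def plot_bias_sweep(df: pd.DataFrame, ax=None):
    """Plot TIER vs bias for each method (machine form of the bias sweep)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for method, grp in df.groupby("method"):
        ax.plot(grp["x_pct"], 100 * grp["tier"], marker="o", label=method)
    ax.axhline(5.0, color="grey", lw=0.8)
    ax.set_xlabel("bias above 0.5 (%)  [B = 0.5(1 + x/100)]")
    ax.set_ylabel("type I error rate (%)")
    ax.legend()
    return ax


def plot_misspec_surface(df: pd.DataFrame, ax=None):
    """Plot TIER vs bias, one line per misspecification percentage."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for pct, grp in df.groupby("pct"):
        ax.plot(grp["x_pct"], 100 * grp["tier"], marker="o", label=f"{pct:g}%")
    ax.axhline(5.0, color="grey", lw=0.8)
    ax.set_xlabel("simulated bias x = 2*100*(B - 0.5)")
    ax.set_ylabel("type I error rate (%)")
    ax.legend(title="q misspecification")
    return ax
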