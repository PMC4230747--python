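"""Model / Results front end, in the style of statsmodels.

Each model class is built from per-exon count data (directly, from a
DataFrame in the canonical table layout, or from TSV files) and ``fit()``
returns a Results object carrying the estimates, their uncertainty, the
allelic-imbalance decision and a ``summary()`` table.

>>> model = PoissonGammaAI(counts, bias=0.5)
>>> res = model.fit(seed=1)
>>> res.ai_flag, res.conf_int()
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import binomial as _binomial
from . import nb as _nb
from . import pg as _pg
from .datamodel import (
    AlleleCounts,
    BiasMode,
    BiasSpec,
    BinomialResult,
    DnaCounts,
    PosteriorResult,
)
from .nb import NBModelSpec
from .pg import PGModelSpec

__all__ = [
    "BinomialAITest",
    "PoissonGammaAI",
    "NegativeBinomialAI",
    "BinomialAITestResults",
    "BayesianAIResults",
]


def _counts_from_dataframe(df: pd.DataFrame, exon_id: str, cls):
    sub = df[df["exon_id"].astype(str) == str(exon_id)].sort_values("replicate")
    if sub.empty:
        raise KeyError(f"exon {exon_id!r} not present in the table")
    m = sub["maternal_count"].to_numpy()
    p = sub["paternal_count"].to_numpy()
    if cls is AlleleCounts:
        return AlleleCounts(exon_id=str(exon_id), x=m, y=p)
    return DnaCounts(exon_id=str(exon_id), x_star=m, y_star=p)


def _fmt(v: float) -> str:
    return f"{v:10.4f}"


class BinomialAITestResults:
    """Results of the pooled binomial test of allelic balance."""

    def __init__(self, result: BinomialResult):
        self._result = result

    @property
    def result(self) -> BinomialResult:
        return self._result

    def __getattr__(self, name):
        return getattr(self._result, name)

    def summary(self) -> str:
        r = self._result
        lines = [
            f"Binomial test of allelic balance ({r.variant} variant)",
            "=" * 54,
            f"exon                 {r.exon_id}",
            f"total reads n        {r.n}",
            f"paternal fraction    {_fmt(r.p_hat)}",
            f"z statistic          {_fmt(r.z)}",
            f"p-value              {_fmt(r.p_value)}",
            f"allelic imbalance    {'yes' if r.ai_flag else 'no'}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        r = self._result
        return (f"<BinomialAITestResults exon={r.exon_id} variant={r.variant} "
                f"p={r.p_value:.4g} ai={r.ai_flag}>")


class BinomialAITest:
    """Pooled binomial test of H0: theta = 1/2 for one exon.

    ``fit(variant="z")`` uses the normal approximation with the
    ``|z| > 1.965`` rule; ``fit(variant="exact")`` the two-sided exact test.
    """

    def __init__(self, counts: AlleleCounts):
        self.counts = counts

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exon_id: str) -> "BinomialAITest":
        return cls(_counts_from_dataframe(df, exon_id, AlleleCounts))

    def fit(self, variant: str = "exact", level: float = 0.05) -> BinomialAITestResults:
        if variant == "z":
            res = _binomial.z_test(self.counts)
        elif variant == "exact":
            res = _binomial.exact_test(self.counts, level=level)
        else:
            raise ValueError(f"variant must be 'z' or 'exact', got {variant!r}")
        return BinomialAITestResults(res)


class BayesianAIResults:
    """Posterior results shared by the PG and NB models.

    Wraps a :class:`~asepg.datamodel.PosteriorResult`; exposes point
    estimates, ``conf_int()`` on either the alpha or the theta scale, the
    AI flag and a ``summary()`` table.
    """

    def __init__(self, result: PosteriorResult, model):
        self._result = result
        self.model = model

    @property
    def result(self) -> PosteriorResult:
        return self._result

    def __getattr__(self, name):
        return getattr(self._result, name)

    def conf_int(self, scale: str = "alpha") -> tuple[float, float]:
        if scale == "alpha":
            return self._result.ci_alpha
        if scale == "theta":
            return self._result.ci_theta
        raise ValueError("scale must be 'alpha' or 'theta'")

    def summary(self) -> str:
        r = self._result
        alo, ahi = r.ci_alpha
        tlo, thi = r.ci_theta
        pct = 100 * r.ci_level
        lines = [
            f"Bayesian allelic-imbalance fit: {r.method}",
            "=" * 60,
            f"exon                     {r.exon_id}",
            f"draws (post burn-in)     {r.n_draws}   burn-in {r.n_burnin}   seed {r.seed}",
            f"alpha (treatment effect) {_fmt(r.alpha_mean)}   "
            f"{pct:.0f}% CI [{alo:.4f}, {ahi:.4f}]",
            f"theta (paternal prop.)   {_fmt(r.theta_mean)}   "
            f"{pct:.0f}% CI [{tlo:.4f}, {thi:.4f}]",
            ("allelic imbalance        yes   (CI for alpha excludes 1)"
             if r.ai_flag else
             "allelic imbalance        no    (CI for alpha contains 1)"),
        ]
        if np.isfinite(r.mu_mean):
            lines.append(f"nuisance mu (post. mean) {_fmt(r.mu_mean)}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        r = self._result
        return (f"<BayesianAIResults {r.method} exon={r.exon_id} "
                f"theta={r.theta_mean:.4f} ai={r.ai_flag}>")


class PoissonGammaAI:
    """The Poisson-Gamma Bayesian model of allelic imbalance for one exon.

    Parameters
    ----------
    counts : AlleleCounts
        Replicated maternal/paternal RNA read counts.
    bias : float, DnaCounts or BiasSpec
        A float fixes q; DNA-control counts select the random-phi variant;
        a BiasSpec states either explicitly.
    spec : PGModelSpec, optional
        Priors and sampler settings (Gamma(1/2, 1/2) priors, 10,000 draws
        after 2,000 burn-in, 95% credible level by default).
    focal : {"paternal", "maternal"}
        Which allele alpha estimates (swap when a global bias direction is
        known and type I error matters more than power).
    """

    def __init__(self, counts: AlleleCounts, bias, spec: PGModelSpec | None = None,
                 focal: str = "paternal"):
        self.counts = counts
        if isinstance(bias, BiasSpec):
            self.bias = bias
        elif isinstance(bias, DnaCounts):
            self.bias = BiasSpec.from_dna(bias)
        else:
            self.bias = BiasSpec.fixed(float(bias))
        self.spec = spec or PGModelSpec()
        self.focal = focal

    @classmethod
    def from_dataframe(cls, rna: pd.DataFrame, exon_id: str, *, q: float | None = None,
                       dna: pd.DataFrame | None = None, **kw) -> "PoissonGammaAI":
        counts = _counts_from_dataframe(rna, exon_id, AlleleCounts)
        if (q is None) == (dna is None):
            raise ValueError("supply exactly one of q and dna")
        bias = (BiasSpec.fixed(q) if q is not None
                else BiasSpec.from_dna(_counts_from_dataframe(dna, exon_id, DnaCounts)))
        return cls(counts, bias, **kw)

    def fit(self, **overrides) -> BayesianAIResults:
        """Run the Gibbs sampler; overrides update the model spec
        (e.g. ``fit(seed=3, n_draws=20_000)``)."""
        spec = self.spec.replace(**overrides) if overrides else self.spec
        res = _pg.fit_pg(self.counts, self.bias, spec, focal=self.focal)
        return BayesianAIResults(res, self)


class NegativeBinomialAI:
    """The Negative Binomial model of allelic imbalance with DNA controls."""

    def __init__(self, counts: AlleleCounts, dna: DnaCounts,
                 spec: NBModelSpec | None = None):
        self.counts = counts
        self.dna = dna
        self.spec = spec or NBModelSpec()

    @classmethod
    def from_dataframe(cls, rna: pd.DataFrame, dna: pd.DataFrame, exon_id: str,
                       **kw) -> "NegativeBinomialAI":
        return cls(
            _counts_from_dataframe(rna, exon_id, AlleleCounts),
            _counts_from_dataframe(dna, exon_id, DnaCounts),
            **kw,
        )

    def fit(self, **overrides) -> BayesianAIResults:
        spec = self.spec.replace(**overrides) if overrides else self.spec
        res = _nb.fit_nb(self.counts, self.dna, spec)
        return BayesianAIResults(res, self)
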