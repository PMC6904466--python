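"""Count-based expression statistics.

Three pieces of machinery, all built on the negative-binomial (NB2) model
``Var(Y) = mu + alpha * mu**2`` with a log link:

* per-gene differential expression between two conditions, producing the
  log2 fold-change ``phi`` and p-value ``pv`` consumed by the GSEA ranking
  metric;
* genotype-stratified association: an NB GLM of expression against genotype
  is compared with an intercept-only model by likelihood ratio, with the
  dispersion estimated under the full model and held fixed for the null fit
  (standard LRT practice, prevents df inflation), and significance from the
  upper tail of the chi-square;
* a paired two-sample comparison (Wilcoxon signed-rank on pair differences,
  exact for small n).

Normalisation uses median-of-ratios size factors. No empirical-Bayes
dispersion shrinkage is applied: each gene's likelihood is self-contained,
which keeps every fit checkable against a direct numerical optimiser (a
deliberate divergence from DESeq2-class moderation).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import ConfigError, DegenerateDesignError, PairingError
from .gsea import RankedGene, rank_metric

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NbGlmFit",
    "LrtResult",
    "PairedTestResult",
    "size_factors",
    "fit_nb_glm",
    "lrt_genotype",
    "paired_test",
    "differential_rank_table",
]

_MIN_ALPHA = 1e-8
_MAX_ALPHA = 1e4


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus per-sample annotations.

    ``samples`` is indexed by sample id and may carry ``condition``,
    ``genotype`` (0/1/2) and ``pair_id`` columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(c.to_numpy().dtype, np.integer):
            if not np.allclose(c.to_numpy(), np.round(c.to_numpy())):
                raise ValueError("counts must be integers")
            self.counts = c.round().astype(np.int64)
        if list(self.samples.index) != list(self.counts.columns):
            raise ValueError("sample annotation does not match count columns")

    @classmethod
    def read_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        counts.columns = counts.columns.astype(str)
        return cls(counts, samples.loc[counts.columns])

    def write_tsv(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t")


@dataclass
class NbGlmFit:
    coef: np.ndarray  # [beta0, beta1, ...] on the natural-log scale
    alpha: float  # NB2 dispersion
    loglik: float
    offsets: np.ndarray
    converged: bool
    mu: np.ndarray


@dataclass
class LrtResult:
    lrt_stat: float
    df: int
    p_chi2: float
    beta1: float
    alpha: float


@dataclass
class PairedTestResult:
    pvalue: float
    n_pairs_used: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference computed over
    genes with no zero count). Falls back to total-count scaling, with a
    warning, when no gene is everywhere nonzero."""
    mat = counts.to_numpy() if hasattr(counts, "to_numpy") else np.asarray(counts)
    mat = mat.astype(float)
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero count")
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        logger.warning(
            "no gene with all-nonzero counts: using total-count size factors"
        )
        totals = mat.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    logs = np.log(mat[allpos])
    ref = logs.mean(axis=1)  # log geometric mean per gene
    return np.exp(np.median(logs - ref[:, None], axis=0))


# ---------------------------------------------------------------------------
# NB likelihood helpers
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; the alpha -> 0 limit is evaluated as Poisson."""
    if alpha < _MIN_ALPHA:
        return float(stats.poisson.logpmf(y, mu).sum())
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(stats.nbinom.logpmf(y, r, p).sum())


def _glm_mu(y, X, offsets, alpha):
    """Coefficients and fitted means of an NB GLM at fixed dispersion."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, _MIN_ALPHA))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=fam, offset=offsets).fit(
            tol=1e-8, maxiter=200
        )
    return np.asarray(res.params), np.asarray(res.mu), res.converged


def _ml_alpha_fit(y, X, offsets):
    """Maximum-likelihood NB fit of coefficients and dispersion.

    Tries the joint MLE (fast); falls back to profiling the likelihood over
    log-dispersion with an inner IRLS fit when the joint optimiser fails or
    wanders off the admissible dispersion range (e.g. near the Poisson
    boundary). Returns (coef, alpha, mu, converged).
    """
    alpha = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, X, offset=offsets)
            res = model.fit(disp=0, maxiter=200, warn_convergence=False)
        a = float(res.params[-1])
        if np.isfinite(a) and _MIN_ALPHA <= a <= _MAX_ALPHA and res.mle_retvals.get(
            "converged", False
        ):
            alpha = a
    except Exception:
        alpha = None
    if alpha is None:
        def profile_nll(log_alpha: float) -> float:
            a = float(np.exp(log_alpha))
            try:
                _, mu, _ = _glm_mu(y, X, offsets, a)
            except Exception:
                return np.inf
            return -nb_loglik(y, mu, a)

        opt = optimize.minimize_scalar(
            profile_nll,
            bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        alpha = float(np.exp(opt.x))
    # coefficients by IRLS at the ML dispersion
    coef, mu, conv = _glm_mu(y, X, offsets, alpha)
    return coef, alpha, mu, bool(conv)


def fit_nb_glm(counts_gene, design=None, offsets=None) -> NbGlmFit:
    """Fit one gene's NB GLM: mean mu = exp(offset + beta0 + beta1 * x).

    ``design`` is a covariate vector (or None for an intercept-only model);
    the dispersion is estimated per gene by maximum likelihood and the
    coefficients by IRLS at that dispersion. Non-convergence is flagged on
    the result, not raised.
    """
    y = np.asarray(counts_gene, dtype=float)
    n = len(y)
    if n < 3:
        raise ConfigError("need at least 3 samples")
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, float)
    if design is None:
        X = np.ones((n, 1))
    else:
        x = np.asarray(design, dtype=float)
        if np.ptp(x) == 0:
            raise DegenerateDesignError("constant covariate in full model")
        X = np.column_stack([np.ones(n), x])
    coef, alpha, mu, conv = _ml_alpha_fit(y, X, offsets)
    return NbGlmFit(
        coef=coef,
        alpha=alpha,
        loglik=nb_loglik(y, mu, alpha),
        offsets=offsets,
        converged=conv,
        mu=mu,
    )


def lrt_genotype(counts_gene, genotype, offsets=None,
                 coding: str = "additive") -> LrtResult:
    """Likelihood-ratio test of genotype against an intercept-only model.

    ``additive`` coding uses the 0/1/2 dosage directly (df = 1);
    ``categorical`` dummy-codes the genotype groups present
    (df = groups - 1). The dispersion is estimated under the full model and
    held fixed for the null fit; p comes from the upper chi-square tail.
    """
    y = np.asarray(counts_gene, dtype=float)
    g = np.asarray(genotype)
    groups = np.unique(g)
    if len(groups) < 2:
        raise DegenerateDesignError("only one genotype group present")
    n = len(y)
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, float)

    if coding == "additive":
        X_full = np.column_stack([np.ones(n), g.astype(float)])
        df = 1
    elif coding == "categorical":
        dummies = np.column_stack(
            [(g == lvl).astype(float) for lvl in groups[1:]]
        )
        X_full = np.column_stack([np.ones(n), dummies])
        df = len(groups) - 1
    else:
        raise ConfigError(f"unknown genotype coding {coding!r}")

    coef_full, alpha, mu_full, _ = _ml_alpha_fit(y, X_full, offsets)
    ll_full = nb_loglik(y, mu_full, alpha)
    _, mu_null, _ = _glm_mu(y, np.ones((n, 1)), offsets, alpha)
    ll_null = nb_loglik(y, mu_null, alpha)

    lrt = 2.0 * (ll_full - ll_null)
    if lrt < -1e-8:
        logger.warning("negative LRT statistic %.3g clipped to 0", lrt)
    lrt = max(lrt, 0.0)
    return LrtResult(
        lrt_stat=float(lrt),
        df=df,
        p_chi2=float(stats.chi2.sf(lrt, df)),
        beta1=float(coef_full[1]),
        alpha=alpha,
    )


def paired_test(values_a, values_b) -> PairedTestResult:
    """Two-sided paired comparison: Wilcoxon signed-rank on pair differences.

    Exact null distribution for up to 25 informative pairs, normal
    approximation with continuity correction beyond; zero differences are
    dropped (Wilcoxon's convention). Identical vectors give the degenerate
    result p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise PairingError("paired vectors differ in length")
    d = a - b
    n_used = int((d != 0).sum())
    if n_used == 0:
        return PairedTestResult(pvalue=1.0, n_pairs_used=0, degenerate=True)
    method = "exact" if n_used <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=True, method=method,
        alternative="two-sided",
    )
    return PairedTestResult(pvalue=float(res.pvalue), n_pairs_used=n_used)


def differential_rank_table(counts, condition,
                            min_count: int = 0) -> list[RankedGene]:
    """Per-gene two-condition NB differential expression, ranked for GSEA.

    ``condition`` maps samples to exactly two groups; for each gene, phi is
    the log2 fold-change (beta1 / ln 2) from an NB GLM with the condition
    coded 0/1, pv the LRT p-value, and pi the combined ranking metric.
    All-zero genes (and genes with total count < ``min_count``) are dropped.
    """
    mat = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    cond = np.asarray(condition)
    levels = np.sort(pd.unique(cond))  # second sorted level = "treatment"
    if len(levels) != 2:
        raise ConfigError("condition must have exactly two groups")
    for lvl in levels:
        if (cond == lvl).sum() < 2:
            logger.warning("condition group %r has < 2 samples", lvl)
    x = (cond == levels[1]).astype(float)
    sf = size_factors(mat)
    offsets = np.log(sf)
    out: list[RankedGene] = []
    ln2 = np.log(2.0)
    for gene_id, row in mat.iterrows():
        y = row.to_numpy(dtype=float)
        if y.sum() == 0 or y.sum() < min_count:
            continue
        res = lrt_genotype(y, x, offsets=offsets, coding="additive")
        phi = res.beta1 / ln2
        pv = max(res.p_chi2, 1e-300)
        out.append(RankedGene(str(gene_id), float(phi), float(pv),
                              float(rank_metric(phi, pv))))
    out.sort(key=lambda g: (-g.pi, g.gene_id))
    return out


def ranked_to_tsv(ranked, path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.phi, g.pv, g.pi) for g in ranked],
        columns=["gene", "phi", "pv", "pi"],
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")
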