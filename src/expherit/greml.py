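"""Per-gene heritability estimators.

Three estimators of expression heritability for an inbred diversity panel:

* repeatability — Pearson/Spearman correlation between biological replicates
  within a condition; an upper bound on h2 for inbred lines.
* two-step GREML — REML on genotype-mean expression with a marker-derived
  relationship matrix K as the covariance of the genetic random effect.
* single-step GREML — REML on the replicate-level observations, so replicate
  variance enters the model directly.

The REML solver follows the efficient mixed-model (EMMA-style) spectral
strategy: the model is

    y = 1*mu + Z g + e,   g ~ N(0, sg2 K),   e ~ N(0, se2 I),

and after one eigendecomposition of the intercept-projected Z K Z' the
restricted log-likelihood becomes a cheap 1-D function of the variance ratio
lambda = sg2/se2, profiled over a log-spaced grid spanning e^-10..e^10 and
refined by bounded scalar minimisation. Heritability is reported on the
observation scale, h2 = sg2/(sg2+se2) = lambda/(1+lambda).

Confidence intervals invert the profile restricted likelihood at the
chi-square(1) 0.95 quantile rather than using curvature: estimates often sit
on the [0, 1] boundary at n = 84, where Wald intervals are meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .grm import GRM
from .io import ExpressionMatrix

LOG_LAMBDA_BOUND = 10.0
N_GRID = 100
_CHI2_95_HALF = stats.chi2.ppf(0.95, df=1) / 2.0


class DegenerateGeneError(ValueError):
    """The response carries no usable variance for variance-component REML."""


@dataclass
class HeritabilityEstimate:
    gene_id: str
    condition: str
    method: str
    h2: float
    sigma_g2: float | None = None
    sigma_e2: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    converged: bool = True
    n_genotypes_used: int = 0
    loglik: float | None = None
    defined: bool = True


@dataclass
class REMLResult:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    converged: bool
    lam: float

    @property
    def h2(self) -> float:
        return self.lam / (1.0 + self.lam)


class SpectralREML:
    """Reusable REML workspace for a fixed kinship/incidence structure.

    One eigendecomposition of S (ZKZ' + I) S, with S the intercept
    projection, serves every response vector sharing the same observation ->
    genotype layout; fitting a new y is then O(n^2) for the rotation plus a
    1-D optimisation. This is what makes 10^4-iteration permutation nulls
    affordable.
    """

    def __init__(self, K: np.ndarray, genotype_of_obs: np.ndarray):
        genotype_of_obs = np.asarray(genotype_of_obs, dtype=int)
        n = genotype_of_obs.size
        if np.unique(genotype_of_obs).size < 3:
            raise ValueError("REML needs at least 3 distinct genotypes")
        H = K[np.ix_(genotype_of_obs, genotype_of_obs)]
        w_min = np.linalg.eigvalsh(K).min()
        if w_min < -1e-8:
            raise ValueError(f"K is not positive semidefinite (min eig {w_min:.3g})")
        A = H + np.eye(n)
        # S A S with S = I - 11'/n, done without forming S
        A = A - A.mean(axis=0, keepdims=True)
        A = A - A.mean(axis=1, keepdims=True)
        w, V = np.linalg.eigh(A)
        # drop the eigenvalue of the intercept null-space; the rest exceed ~1
        self.xi = np.clip(w[1:] - 1.0, 0.0, None)
        self.U = V[:, 1:]
        self.n = n
        self.df = n - 1
        self.genotype_of_obs = genotype_of_obs
        self._grid_log_lam = np.linspace(-LOG_LAMBDA_BOUND, LOG_LAMBDA_BOUND, N_GRID)

    def _loglik_from_eta2(self, eta2: np.ndarray, log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = lam * self.xi + 1.0
        r = float(np.sum(eta2 / d))
        df = self.df
        return 0.5 * (
            df * np.log(df / (2.0 * np.pi)) - df - df * np.log(r) - float(np.sum(np.log(d)))
        )

    def fit(self, y: np.ndarray, compute_ci: bool = False) -> REMLResult | tuple:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("response length does not match workspace")
        eta2 = (self.U.T @ y) ** 2
        tot = float(eta2.sum())
        if not np.isfinite(tot) or tot <= 1e-12 * max(1.0, float(y @ y)):
            raise DegenerateGeneError("response has no variance after projection")

        lls = np.array([self._loglik_from_eta2(eta2, t) for t in self._grid_log_lam])
        i = int(np.argmax(lls))
        lo = self._grid_log_lam[max(i - 1, 0)]
        hi = self._grid_log_lam[min(i + 1, N_GRID - 1)]
        res = optimize.minimize_scalar(
            lambda t: -self._loglik_from_eta2(eta2, t),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        log_lam = float(res.x)
        ll = -float(res.fun)
        # boundary solutions are valid REML optima on the closed box
        if i == 0 and lls[0] >= ll:
            log_lam, ll = self._grid_log_lam[0], lls[0]
        elif i == N_GRID - 1 and lls[-1] >= ll:
            log_lam, ll = self._grid_log_lam[-1], lls[-1]

        lam = float(np.exp(log_lam))
        se2 = float(np.sum(eta2 / (lam * self.xi + 1.0))) / self.df
        sg2 = lam * se2
        at_lower = log_lam <= -LOG_LAMBDA_BOUND + 1e-6
        if at_lower:
            sg2, lam = 0.0, 0.0
        result = REMLResult(sg2, se2, ll, True, lam)
        if not compute_ci:
            return result
        return result, self._profile_ci(eta2, log_lam if not at_lower else -LOG_LAMBDA_BOUND, ll)

    def _profile_ci(self, eta2: np.ndarray, log_lam_hat: float, ll_max: float):
        """Invert the profile likelihood at chi2(1) 0.95; bounds on h2 scale."""
        target = ll_max - _CHI2_95_HALF

        def g(t: float) -> float:
            return self._loglik_from_eta2(eta2, t) - target

        b = LOG_LAMBDA_BOUND
        if g(-b) >= 0:
            lo_h2 = 0.0
        else:
            t_lo = optimize.brentq(g, -b, log_lam_hat, xtol=1e-10)
            lo_h2 = float(np.exp(t_lo) / (1.0 + np.exp(t_lo)))
        if g(b) >= 0:
            hi_h2 = 1.0
        else:
            t_hi = optimize.brentq(g, log_lam_hat, b, xtol=1e-10)
            hi_h2 = float(np.exp(t_hi) / (1.0 + np.exp(t_hi)))
        return lo_h2, hi_h2


def reml_fit(y: np.ndarray, genotype_of_obs: np.ndarray, K: np.ndarray) -> REMLResult:
    """One-shot REML fit; see SpectralREML for the reusable form."""
    return SpectralREML(K, genotype_of_obs).fit(y)


# ---------------------------------------------------------------------------
# estimators on the expression container


def heritability_gene_filter(expr: ExpressionMatrix, max_missing: float = 0.05) -> list[str]:
    """Genes with < max_missing missing rate across all samples (strict)."""
    rate = expr.missing_mask.mean(axis=1)
    return [g for g, r in zip(expr.gene_ids, rate) if r < max_missing]


def repeatability(
    expr: ExpressionMatrix, gene_id: str, condition: str, method: str = "pearson"
) -> HeritabilityEstimate:
    """Replicate-replicate correlation across genotypes for one gene.

    Pairs with any masked member are dropped; zero variance in either
    replicate vector yields a flagged undefined estimate rather than an
    exception (constant genes are a real occurrence, not a caller bug).
    """
    rm = expr.replicate_matrix(gene_id, condition)
    if rm.shape[1] != 2:
        raise ValueError("repeatability requires exactly 2 replicates")
    paired = rm.dropna()
    name = f"repeatability_{method}"
    if len(paired) < 3:
        raise ValueError(f"gene {gene_id}: fewer than 3 complete replicate pairs")
    x = paired.iloc[:, 0].to_numpy()
    y = paired.iloc[:, 1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return HeritabilityEstimate(
            gene_id, condition, name, np.nan, defined=False, n_genotypes_used=len(paired)
        )
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown repeatability method {method!r}")
    return HeritabilityEstimate(gene_id, condition, name, r, n_genotypes_used=len(paired))


def _gene_observations(expr: ExpressionMatrix, gene_id: str, condition: str, grm: GRM):
    """Unmasked observations for one gene/condition, as (y, genotype indices)."""
    i = expr.gene_index(gene_id)
    cols = expr.sample_columns(condition=condition)
    if cols.size == 0:
        raise ValueError(f"condition {condition!r} absent from samples")
    gidx_of = {g: j for j, g in enumerate(grm.genotype_ids)}
    ys, gidx = [], []
    for j in cols:
        if expr.missing_mask[i, j]:
            continue
        g = expr.samples[j].genotype_id
        if g not in gidx_of:
            raise KeyError(f"genotype {g!r} absent from GRM")
        ys.append(expr.values[i, j])
        gidx.append(gidx_of[g])
    return np.asarray(ys), np.asarray(gidx, dtype=int)


def _estimate(gene_id, condition, method, y, gidx, K, workspace=None, compute_ci=True):
    ws = workspace if workspace is not None else SpectralREML(K, gidx)
    try:
        fit = ws.fit(y, compute_ci=compute_ci)
    except DegenerateGeneError:
        return HeritabilityEstimate(gene_id, condition, method, np.nan, defined=False)
    if compute_ci:
        fit, (lo, hi) = fit
        lo, hi = min(lo, fit.h2), max(hi, fit.h2)
    else:
        lo = hi = None
    return HeritabilityEstimate(
        gene_id, condition, method, float(fit.h2),
        sigma_g2=fit.sigma_g2, sigma_e2=fit.sigma_e2,
        ci_low=lo, ci_high=hi, converged=fit.converged,
        n_genotypes_used=int(np.unique(gidx).size), loglik=fit.loglik,
    )


def estimate_h2_two_step(
    expr: ExpressionMatrix, gene_id: str, condition: str, grm: GRM,
    workspace: SpectralREML | None = None, compute_ci: bool = True,
) -> HeritabilityEstimate:
    """GREML on genotype-mean expression (one observation per genotype)."""
    y, gidx = _gene_observations(expr, gene_id, condition, grm)
    means: dict[int, list[float]] = {}
    for v, g in zip(y, gidx):
        means.setdefault(int(g), []).append(v)
    gs = sorted(means)
    ybar = np.array([np.mean(means[g]) for g in gs])
    gvec = np.array(gs, dtype=int)
    return _estimate(gene_id, condition, "greml_two_step", ybar, gvec, grm.K,
                     workspace=workspace, compute_ci=compute_ci)


def estimate_h2_single_step(
    expr: ExpressionMatrix, gene_id: str, condition: str, grm: GRM,
    workspace: SpectralREML | None = None, compute_ci: bool = True,
) -> HeritabilityEstimate:
    """GREML on replicate-level observations (replicate variance in-model)."""
    y, gidx = _gene_observations(expr, gene_id, condition, grm)
    return _estimate(gene_id, condition, "greml_single_step", y, gidx, grm.K,
                     workspace=workspace, compute_ci=compute_ci)


def h2_table(
    expr: ExpressionMatrix,
    grm: GRM,
    methods: tuple[str, ...] = ("repeatability_pearson", "greml_single_step"),
    conditions: tuple[str, ...] | None = None,
    max_missing: float = 0.05,
    compute_ci: bool = False,
):
    """Estimate heritability for every gene passing the missingness filter.

    Returns a tidy DataFrame (gene_id, condition, method, h2, ...). REML
    workspaces are cached by missingness pattern, so a transcriptome of
    mostly complete genes costs one eigendecomposition per condition.
    """
    import pandas as pd

    conditions = tuple(conditions or expr.conditions)
    genes = heritability_gene_filter(expr, max_missing)
    cache: dict[tuple, SpectralREML] = {}
    rows = []
    for cond in conditions:
        for gene in genes:
            for method in methods:
                if method.startswith("repeatability"):
                    est = repeatability(expr, gene, cond, method.split("_", 1)[1])
                else:
                    fn = (
                        estimate_h2_single_step
                        if method == "greml_single_step"
                        else estimate_h2_two_step
                    )
                    y, gidx = _gene_observations(expr, gene, cond, grm)
                    if method == "greml_two_step":
                        key = (cond, "two", tuple(np.unique(gidx)))
                    else:
                        key = (cond, "one", tuple(gidx))
                    if key not in cache:
                        if method == "greml_two_step":
                            cache[key] = SpectralREML(grm.K, np.unique(gidx))
                        else:
                            cache[key] = SpectralREML(grm.K, gidx)
                    est = fn(expr, gene, cond, grm, workspace=cache[key], compute_ci=compute_ci)
                rows.append(
                    {
                        "gene_id": est.gene_id,
                        "condition": est.condition,
                        "method": est.method,
                        "h2": est.h2,
                        "sigma_g2": est.sigma_g2,
                        "sigma_e2": est.sigma_e2,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "converged": est.converged,
                        "defined": est.defined,
                        "n_genotypes_used": est.n_genotypes_used,
                    }
                )
    return pd.DataFrame(rows)
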