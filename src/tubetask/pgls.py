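"""PGLS regression with a Pagel's-lambda correlation structure, AICc model
ranking, Akaike weights, and conditional model averaging.

A species-level response (MeanHI or MeanAbsHI) is regressed on up to three
predictors — ecology (0 = arboreal, 1 = terrestrial), habitual
foraging-related tool use (0/1), and log10 female endocranial volume — with
residuals correlated according to the lambda-scaled phylogenetic covariance.
All 2^p predictor subsets (including the intercept-only NULL model) are fit
by maximum likelihood with lambda optimized per model, ranked by the
small-sample Akaike criterion

    AICc = -2 logL + 2k + 2k(k + 1) / (n - k - 1),

where k counts the intercept, the slopes, and the residual variance (not
lambda, matching the df convention of the multi-model-inference tooling this
mirrors).  Per-term effects are summarized by the conditional model average:
a weighted mean over only the models containing the term, with renormalized
Akaike weights and the revised model-averaging variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import PredictorRecord
from .phylo import Phylogeny, lambda_transform, _LAMBDA_GRID, _LAMBDA_XATOL
from scipy import optimize

TERMS = ("ecology", "tool_use", "log_brain")


class RankDeficientError(ValueError):
    pass


def design_matrix(
    species: Sequence[str],
    predictors: Mapping[str, PredictorRecord],
    terms: Sequence[str],
) -> np.ndarray:
    """Intercept-first design matrix in the given species order."""
    missing = [s for s in species if s not in predictors]
    if missing:
        raise ValueError(f"missing predictor rows for: {missing}")
    cols = [np.ones(len(species))]
    for t in terms:
        if t == "ecology":
            cols.append(np.array(
                [1.0 if predictors[s].ecology == "terrestrial" else 0.0
                 for s in species]))
        elif t == "tool_use":
            cols.append(np.array(
                [1.0 if predictors[s].tool_use else 0.0 for s in species]))
        elif t == "log_brain":
            cols.append(np.array(
                [np.log10(predictors[s].brain_size_ml) for s in species]))
        else:
            raise ValueError(f"unknown term {t!r}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError(
            f"design matrix is rank deficient for terms {tuple(terms)}")
    return X


@dataclass(frozen=True)
class PGLSFit:
    response: str
    terms: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    std_errors: np.ndarray
    lambda_hat: float
    sigma2_hat: float
    loglik: float
    n: int

    @property
    def k(self) -> int:
        return len(self.terms) + 2  # intercept + slopes + residual variance

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term) + 1])

    def se(self, term: str) -> float:
        return float(self.std_errors[self.terms.index(term) + 1])


def _gls_at_lambda(y, X, C, lam):
    """GLS estimates and ML log-likelihood at fixed lambda."""
    n = y.size
    V = lambda_transform(C, lam)
    L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
    return beta, rss, sigma2_ml, float(ll), Xw


def pgls_fit(
    y: Mapping[str, float],
    terms: Sequence[str],
    predictors: Mapping[str, PredictorRecord],
    tree: Phylogeny,
    response: str = "trait",
    fixed_lambda: float | None = None,
) -> PGLSFit:
    """Joint-ML PGLS fit with lambda optimized on [0, 1] (or held fixed).

    Standard errors use the unbiased residual variance RSS / (n - p) on the
    whitened scale; the log-likelihood reported is the ML one used for AICc.
    """
    species = sorted(y)
    yv = np.array([y[s] for s in species], dtype=float)
    X = design_matrix(species, predictors, terms)
    C = tree.vcv(species)

    if fixed_lambda is not None:
        lam_hat = fixed_lambda
        ll_hat = _gls_at_lambda(yv, X, C, lam_hat)[3]
    else:
        grid_ll = [_gls_at_lambda(yv, X, C, lam)[3] for lam in _LAMBDA_GRID]
        best = int(np.argmax(grid_ll))
        lo = _LAMBDA_GRID[max(best - 1, 0)]
        hi = _LAMBDA_GRID[min(best + 1, len(_LAMBDA_GRID) - 1)]
        res = optimize.minimize_scalar(
            lambda lam: -_gls_at_lambda(yv, X, C, lam)[3],
            bounds=(lo, hi), method="bounded",
            options={"xatol": _LAMBDA_XATOL},
        )
        ll_hat, lam_hat = max(
            [(grid_ll[best], _LAMBDA_GRID[best]), (-float(res.fun), float(res.x))]
        )
    beta, rss, sigma2_ml, ll_hat, Xw = _gls_at_lambda(yv, X, C, lam_hat)
    n, p = yv.size, X.shape[1]
    sigma2_unbiased = rss / (n - p)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(sigma2_unbiased * XtX_inv))
    return PGLSFit(
        response=response,
        terms=tuple(terms),
        coefficients=beta,
        std_errors=se,
        lambda_hat=float(lam_hat),
        sigma2_hat=float(sigma2_ml),
        loglik=float(ll_hat),
        n=n,
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Relative model support: w_m proportional to exp(-delta_m / 2)."""
    a = np.asarray(aiccs, dtype=float)
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


def enumerate_models(terms: Sequence[str] = TERMS) -> list[tuple[str, ...]]:
    """All predictor subsets, from the NULL model to the full model."""
    out = []
    for r in range(len(terms) + 1):
        out.extend(itertools.combinations(terms, r))
    return out


@dataclass
class ModelSelectionTable:
    """Per-model fits sorted by AICc; ties break toward fewer terms."""

    fits: list[PGLSFit]
    rows: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        order = sorted(
            range(len(self.fits)),
            key=lambda i: (self.fits[i].aicc, len(self.fits[i].terms),
                           self.fits[i].terms),
        )
        self.fits = [self.fits[i] for i in order]
        aiccs = np.array([f.aicc for f in self.fits])
        w = akaike_weights(aiccs)
        self.rows = pd.DataFrame(
            {
                "terms": [", ".join(f.terms) if f.terms else "(NULL)"
                          for f in self.fits],
                "df": [f.k for f in self.fits],
                "aicc": aiccs,
                "delta_aicc": aiccs - aiccs.min(),
                "weight": w,
            }
        )

    @property
    def weights(self) -> np.ndarray:
        return self.rows["weight"].to_numpy()


@dataclass(frozen=True)
class AveragedCoefficient:
    term: str
    estimate: float
    std_error: float
    vif: float
    p: float


def conditional_average(
    table: ModelSelectionTable,
    vifs: Mapping[str, float] | None = None,
) -> dict[str, AveragedCoefficient]:
    """Conditional model average of each term's coefficient.

    Only models containing the term contribute, with weights renormalized
    over that subset.  The adjusted standard error combines each model's
    sampling variance with the squared deviation of its estimate from the
    average (revised model-averaging variance); p-values use a normal
    reference.
    """
    all_terms = sorted({t for f in table.fits for t in f.terms})
    out = {}
    for term in all_terms:
        idx = [i for i, f in enumerate(table.fits) if term in f.terms]
        if not idx:
            raise ValueError(f"term {term!r} absent from all models")
        w = table.weights[idx]
        w = w / w.sum()
        betas = np.array([table.fits[i].coef(term) for i in idx])
        ses = np.array([table.fits[i].se(term) for i in idx])
        est = float(w @ betas)
        var = float(w @ (ses**2 + (betas - est) ** 2))
        se = float(np.sqrt(var))
        z = est / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        out[term] = AveragedCoefficient(
            term=term,
            estimate=est,
            std_error=se,
            vif=float(vifs.get(term, np.nan)) if vifs else np.nan,
            p=p,
        )
    return out


def vif(X: np.ndarray, terms: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors; X has the intercept in column 0."""
    out = {}
    n_terms = X.shape[1] - 1
    if len(terms) != n_terms:
        raise ValueError("terms must name the non-intercept columns")
    for j in range(1, X.shape[1]):
        target = X[:, j]
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        if ss_tot == 0.0:
            raise RankDeficientError(f"constant predictor column {terms[j-1]!r}")
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            raise RankDeficientError(
                f"perfect collinearity involving {terms[j-1]!r}")
        out[terms[j - 1]] = 1.0 / (1.0 - r2)
    return out


def shapiro_wilk(residuals: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test of model residuals."""
    x = np.asarray(residuals, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk p-value unreliable for n > 5000")
    w, p = stats.shapiro(x)
    return float(w), float(p)


@dataclass
class ModelSuiteResult:
    response: str
    n: int
    table: ModelSelectionTable
    averaged: dict[str, AveragedCoefficient]
    vifs: dict[str, float]
    shapiro: tuple[float, float]

    def averaged_frame(self) -> pd.DataFrame:
        rows = [self.averaged[t] for t in sorted(self.averaged)]
        return pd.DataFrame(
            {
                "term": [r.term for r in rows],
                "estimate": [r.estimate for r in rows],
                "std_error": [r.std_error for r in rows],
                "vif": [r.vif for r in rows],
                "p": [r.p for r in rows],
            }
        )


def run_analysis(
    y: Mapping[str, float],
    predictors: Mapping[str, PredictorRecord],
    tree: Phylogeny,
    response: str,
    terms: Sequence[str] = TERMS,
) -> ModelSuiteResult:
    """All-subsets PGLS for one response: table, averages, VIF, residual check."""
    fits = [
        pgls_fit(y, m, predictors, tree, response=response)
        for m in enumerate_models(terms)
    ]
    table = ModelSelectionTable(fits)
    species = sorted(y)
    X_full = design_matrix(species, predictors, terms)
    vifs = vif(X_full, terms)
    averaged = conditional_average(table, vifs)
    # residual check on the best model (whitened residuals)
    best = table.fits[0]
    yv = np.array([y[s] for s in species])
    Xb = design_matrix(species, predictors, best.terms)
    C = tree.vcv(species)
    V = lambda_transform(C, best.lambda_hat)
    L = np.linalg.cholesky(V)
    resid = np.linalg.solve(L, yv) - np.linalg.solve(L, Xb) @ best.coefficients
    return ModelSuiteResult(
        response=response,
        n=len(species),
        table=table,
        averaged=averaged,
        vifs=vifs,
        shapiro=shapiro_wilk(resid),
    )


def run_model_suite(
    summaries,
    predictors: Mapping[str, PredictorRecord],
    tree: Phylogeny,
    min_n_direction: int = 15,
    human: str = "Homo sapiens",
) -> dict[str, ModelSuiteResult]:
    """The three published analyses: direction (n>=15 species, with humans),
    direction without humans, and strength (all species)."""
    strength = {s.group_id: s.mean_abs_hi for s in summaries}
    direction = {s.group_id: s.mean_hi for s in summaries if s.n >= min_n_direction}
    direction_nh = {k: v for k, v in direction.items() if k != human}
    return {
        "direction": run_analysis(direction, predictors, tree, "MeanHI"),
        "direction_no_humans": run_analysis(direction_nh, predictors, tree, "MeanHI"),
        "strength": run_analysis(strength, predictors, tree, "MeanAbsHI"),
    }
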