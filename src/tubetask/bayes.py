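"""Bayesian phylogenetic multilevel regression of individual laterality.

Model (per subject i, species s(i)):

    y_i = b0 + b_age * subadult_i + b_sex * male_i + u_{s(i)} + e_i
    u ~ MVN(0, sigma_species^2 * A),   e_i ~ N(0, sigma_resid^2)

where A is the phylogenetic correlation matrix (the tree's variance-
covariance matrix scaled to unit diagonal), so sigma_species measures the
phylogenetically structured between-species spread on the response scale.
The response y is either the subject's HI (direction) or |HI| (strength).

Sampling is blocked Gibbs: the regression coefficients (flat prior) and the
species effects have conjugate Gaussian full conditionals; the two standard
deviations carry half-Student-t(3, 0, 2.5) priors and are updated by slice
sampling on the log scale.  Convergence is summarized with split R-hat and
effective sample size.

Exclusions mirror the study design: humans (extreme outlier), chimpanzees
(strongly overrepresented), Tonkean macaques (no age data), and unsexed
subjects are removed before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data_io import SubjectRecord
from .laterality import handedness_index
from .phylo import Phylogeny

DEFAULT_EXCLUDED_SPECIES = ("Homo sapiens", "Pan troglodytes", "Macaca tonkeana")

CLADE_SCOPES = ("all", "Hominoidea", "Cercopithecoidea", "Platyrrhini")


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    prior_scale_intercept: float = 2.5
    prior_scale_sd: float = 2.5
    prior_df: float = 3.0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("warmup must lie in (0, iterations)")


def build_bayes_dataset(
    subjects: Sequence[SubjectRecord],
    scope: str = "all",
    excluded_species: Sequence[str] = DEFAULT_EXCLUDED_SPECIES,
) -> pd.DataFrame:
    """Model-ready table with HI/AbsHI responses and age/sex dummies.

    Removes the excluded species and unsexed subjects, then restricts to the
    requested clade scope.  Subjects without an age class are also dropped
    since age is a model term.
    """
    if scope not in CLADE_SCOPES:
        raise ValueError(f"scope must be one of {CLADE_SCOPES}")
    rows = []
    for s in subjects:
        if s.species in excluded_species or s.sex not in ("F", "M"):
            continue
        if s.age_class not in ("adult", "subadult"):
            continue
        if scope != "all" and s.clade != scope:
            continue
        hi = handedness_index(s.right_insertions, s.left_insertions)
        rows.append(
            {
                "subject_id": s.subject_id,
                "species": s.species,
                "clade": s.clade,
                "hi": hi,
                "abs_hi": abs(hi),
                "subadult": 1.0 if s.age_class == "subadult" else 0.0,
                "male": 1.0 if s.sex == "M" else 0.0,
            }
        )
    if not rows:
        raise ValueError(f"no subjects left after exclusions (scope={scope})")
    return pd.DataFrame(rows)


PARAM_NAMES = ("intercept", "beta_age", "beta_sex", "sigma_species", "sigma_resid")


@dataclass
class PosteriorDraws:
    """MCMC draws (chains x draws) per parameter plus diagnostics."""

    draws: dict[str, np.ndarray]  # each (chains, kept_draws)
    species: list[str]
    u_draws: np.ndarray  # (chains, kept_draws, n_species)
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)

    def pooled(self, parameter: str) -> np.ndarray:
        if parameter not in self.draws:
            raise KeyError(f"unknown parameter {parameter!r}")
        return self.draws[parameter].reshape(-1)

    def converged(self, threshold: float = 1.01) -> bool:
        return all(r <= threshold for r in self.rhat.values())

    def to_frame(self) -> pd.DataFrame:
        """One row per draw per chain, for CSV export."""
        chains, n = next(iter(self.draws.values())).shape
        out = {"chain": np.repeat(np.arange(chains), n),
               "draw": np.tile(np.arange(n), chains)}
        for k, v in self.draws.items():
            out[k] = v.reshape(-1)
        return pd.DataFrame(out)


def _half_t_logpdf(s: float, df: float, scale: float) -> float:
    if s <= 0:
        return -np.inf
    return float(-0.5 * (df + 1.0) * np.log1p((s / scale) ** 2 / df))


def _slice_sample_log_sd(
    log_s0: float, logpost, rng: np.random.Generator, width: float = 1.0,
    max_steps: int = 50,
) -> float:
    """Univariate slice sampler (stepping out) on log sigma."""
    y = logpost(log_s0) + np.log(rng.uniform())
    lo = log_s0 - width * rng.uniform()
    hi = lo + width
    for _ in range(max_steps):
        if logpost(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if logpost(hi) <= y:
            break
        hi += width
    while True:
        prop = rng.uniform(lo, hi)
        if logpost(prop) > y:
            return prop
        if prop < log_s0:
            lo = prop
        else:
            hi = prop


def sample_posterior(
    table: pd.DataFrame,
    tree: Phylogeny,
    response: Literal["hi", "abs_hi"],
    config: MCMCConfig = MCMCConfig(),
    strict: bool = False,
    fix_sigma_species: float | None = None,
) -> PosteriorDraws:
    """Gibbs/slice sampler for the phylogenetic multilevel model.

    ``fix_sigma_species`` pins the between-species SD (0 reduces the model
    to ordinary linear regression; useful for validation).
    """
    species = sorted(table["species"].unique())
    missing = set(species) - set(tree.tips)
    if missing:
        raise ValueError(f"species not on tree: {sorted(missing)}")
    y = table[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(table)), table["subadult"].to_numpy(), table["male"].to_numpy()]
    )
    sp_idx = np.array([species.index(s) for s in table["species"]])
    n, p = X.shape
    n_sp = len(species)

    C = tree.vcv(species)
    d = np.sqrt(np.diag(C))
    A = C / np.outer(d, d)  # correlation matrix
    A_inv = np.linalg.inv(A + 1e-10 * np.eye(n_sp))

    XtX = X.T @ X
    counts = np.bincount(sp_idx, minlength=n_sp).astype(float)
    Z_sum = lambda v: np.bincount(sp_idx, weights=v, minlength=n_sp)
    ZtX = np.column_stack([Z_sum(X[:, j]) for j in range(p)])
    Zty = Z_sum(y)
    Xty = X.T @ y

    kept = config.iterations - config.warmup
    draws = {k: np.empty((config.chains, kept)) for k in PARAM_NAMES}
    u_draws = np.empty((config.chains, kept, n_sp))

    for chain in range(config.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, chain]))
        beta = np.zeros(p)
        u = np.zeros(n_sp)
        sigma_e = max(float(np.std(y)), 1e-3)
        sigma_s = sigma_e / 2.0

        if fix_sigma_species is not None:
            sigma_s = float(fix_sigma_species)

        for it in range(config.iterations):
            # beta | sigmas  (species effects integrated out via Woodbury,
            # so the intercept does not random-walk against mean(u))
            if sigma_s > 0.0:
                W = A_inv / sigma_s**2 + np.diag(counts) / sigma_e**2
                W_inv_ZtX = np.linalg.solve(W, ZtX)
                W_inv_Zty = np.linalg.solve(W, Zty)
                XtSiX = XtX / sigma_e**2 - ZtX.T @ W_inv_ZtX / sigma_e**4
                XtSiy = Xty / sigma_e**2 - ZtX.T @ W_inv_Zty / sigma_e**4
            else:
                XtSiX = XtX / sigma_e**2
                XtSiy = Xty / sigma_e**2
            cov = np.linalg.inv(XtSiX)
            mean = cov @ XtSiy
            beta = rng.multivariate_normal(mean, cov, method="cholesky")

            # u | rest
            resid_b = y - X @ beta
            if sigma_s > 0.0:
                prec = A_inv / sigma_s**2 + np.diag(counts) / sigma_e**2
                Lp = np.linalg.cholesky(prec)
                rhs = Z_sum(resid_b) / sigma_e**2
                mu_u = np.linalg.solve(Lp.T, np.linalg.solve(Lp, rhs))
                u = mu_u + np.linalg.solve(Lp.T, rng.standard_normal(n_sp))
            else:
                u = np.zeros(n_sp)

            # sigma_resid | rest (slice on log scale, half-t prior)
            err = resid_b - u[sp_idx]
            sse = float(err @ err)

            def lp_e(ls):
                s = np.exp(ls)
                return (-n * ls - sse / (2.0 * s**2)
                        + _half_t_logpdf(s, config.prior_df,
                                         config.prior_scale_sd) + ls)

            sigma_e = float(np.exp(_slice_sample_log_sd(np.log(sigma_e), lp_e, rng)))

            # sigma_species | rest
            if fix_sigma_species is None:
                quad = float(u @ A_inv @ u)

                def lp_s(ls):
                    s = np.exp(ls)
                    return (-n_sp * ls - quad / (2.0 * s**2)
                            + _half_t_logpdf(s, config.prior_df,
                                             config.prior_scale_sd) + ls)

                sigma_s = float(np.exp(
                    _slice_sample_log_sd(np.log(sigma_s), lp_s, rng)))

            if it >= config.warmup:
                j = it - config.warmup
                draws["intercept"][chain, j] = beta[0]
                draws["beta_age"][chain, j] = beta[1]
                draws["beta_sex"][chain, j] = beta[2]
                draws["sigma_species"][chain, j] = sigma_s
                draws["sigma_resid"][chain, j] = sigma_e
                u_draws[chain, j] = u

    result = PosteriorDraws(draws=draws, species=species, u_draws=u_draws)
    _attach_diagnostics(result)
    if not result.converged():
        bad = {k: v for k, v in result.rhat.items() if v > 1.01}
        msg = f"R-hat above 1.01 for: {bad}"
        if strict:
            raise ConvergenceError(msg)
        warnings.warn(msg)
    return result


def _attach_diagnostics(result: PosteriorDraws) -> None:
    import arviz as az

    ds = az.convert_to_dataset({k: v for k, v in result.draws.items()})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    for k, v in result.draws.items():
        r = float(rhat[k].values)
        if np.isnan(r) and np.ptp(v) == 0.0:  # pinned parameter
            r = 1.0
        result.rhat[k] = r
        result.ess[k] = float(ess[k].values)


@dataclass(frozen=True)
class EffectSummary:
    parameter: str
    mean: float
    lower: float  # 2.5%
    upper: float  # 97.5%

    @property
    def notable(self) -> bool:
        """Notable effect: the equal-tailed 95% interval excludes zero."""
        return self.lower > 0.0 or self.upper < 0.0


def summarize_effect(draws: PosteriorDraws, parameter: str) -> EffectSummary:
    x = draws.pooled(parameter)
    lo, hi = np.quantile(x, [0.025, 0.975])
    return EffectSummary(parameter, float(x.mean()), float(lo), float(hi))


def summary_json(draws: PosteriorDraws) -> dict:
    out = {}
    for k in PARAM_NAMES:
        s = summarize_effect(draws, k)
        out[k] = {
            "mean": s.mean,
            "ci_2.5%": s.lower,
            "ci_97.5%": s.upper,
            "notable": s.notable,
            "rhat": draws.rhat[k],
            "ess": draws.ess[k],
        }
    return out
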