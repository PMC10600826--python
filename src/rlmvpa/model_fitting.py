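"""Hierarchical empirical-Bayes fitting of the RW variant family, plus AIC
model comparison.

Fitting alternates per-subject MAP estimation (multi-start quasi-Newton in
unconstrained space, Laplace curvature at the optimum) with closed-form
updates of a diagonal Gaussian population prior over the unconstrained
parameters — an EM approximation to full hierarchical Bayesian inference.
Model comparison uses summed AIC with near-maximum-likelihood deviances
obtained by refitting each subject under a deflated (variance x100) prior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._errors import FitError, InputError, ParameterError
from .rl_models import (
    AgentParams,
    ModelSpec,
    from_unconstrained,
    negloglik_arrays,
    _trial_arrays,
)

_HESS_STEP = 1e-4
_CURV_FLOOR = 1e-6
_VAR_FLOOR = 1e-4


@dataclass(frozen=True)
class PopulationPrior:
    """Diagonal Gaussian over unconstrained parameters (logit alphas, log beta)."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        var = np.atleast_1d(np.asarray(self.var, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "var", var)
        if mean.shape != var.shape:
            raise ParameterError("prior mean/var shape mismatch")
        if np.any(var <= 0):
            raise ParameterError("prior variances must be positive")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def neg_logpdf(self, theta: np.ndarray) -> float:
        d = theta - self.mean
        return float(0.5 * np.sum(d * d / self.var + np.log(2 * np.pi * self.var)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean, np.sqrt(self.var), size=(n, self.dim))

    def deflated(self, factor: float = 100.0) -> "PopulationPrior":
        return PopulationPrior(self.mean, self.var * factor)

    @classmethod
    def default(cls, spec: ModelSpec) -> "PopulationPrior":
        return cls(np.zeros(spec.n_params), np.full(spec.n_params, 4.0))


@dataclass
class SubjectFit:
    subject: int
    spec: ModelSpec
    theta: np.ndarray  # MAP in unconstrained space
    params: AgentParams  # MAP on the natural scale
    nll_map: float  # data NLL at the MAP (no prior term)
    objective: float  # penalized objective (NLL + prior) at the MAP
    hess_diag: np.ndarray  # Laplace curvature of the penalized objective
    n_trials: int
    converged: bool
    nll_ml: float | None = None  # near-ML NLL (deflated-prior refit)
    aic: float | None = None

    def finish_aic(self, nll_ml: float) -> None:
        self.nll_ml = float(nll_ml)
        self.aic = 2.0 * self.spec.n_params + 2.0 * float(nll_ml)


@dataclass
class CohortFit:
    spec: ModelSpec
    prior: PopulationPrior
    subject_fits: list[SubjectFit]
    summed_aic: float
    converged: bool
    log: list[dict] = field(default_factory=list)

    @property
    def subjects(self) -> list[int]:
        return [f.subject for f in self.subject_fits]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [f.subject for f in self.subject_fits],
                "spec": [f.spec.name for f in self.subject_fits],
                "alpha_pos": [f.params.alpha_pos for f in self.subject_fits],
                "alpha_neg": [f.params.alpha_neg for f in self.subject_fits],
                "beta": [f.params.beta for f in self.subject_fits],
                "nll": [f.nll_ml for f in self.subject_fits],
                "aic": [f.aic for f in self.subject_fits],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec.name,
                "prior_mean": self.prior.mean.tolist(),
                "prior_var": self.prior.var.tolist(),
                "summed_aic": self.summed_aic,
                "converged": self.converged,
                "subjects": [
                    {
                        "subject": f.subject,
                        "theta": f.theta.tolist(),
                        "alpha_pos": f.params.alpha_pos,
                        "alpha_neg": f.params.alpha_neg,
                        "beta": f.params.beta,
                        "nll_map": f.nll_map,
                        "nll_ml": f.nll_ml,
                        "aic": f.aic,
                    }
                    for f in self.subject_fits
                ],
                "log": self.log,
            }
        )


def _penalized_objective(spec, prior, choices, outcomes, n_arms):
    # hot path: transforms and prior inlined to avoid per-eval object churn
    from .rl_models import _nll_core

    cf, rs = spec.counterfactual, spec.risk_sensitive
    mean, var = prior.mean, prior.var
    log_norm = 0.5 * float(np.log(2 * np.pi * var).sum())

    def fun(theta: np.ndarray) -> float:
        # expit via tanh: overflow-safe for arbitrarily large |theta|
        a_pos = 0.5 * (1.0 + math.tanh(0.5 * theta[0]))
        a_neg = 0.5 * (1.0 + math.tanh(0.5 * theta[1])) if rs else a_pos
        lb = theta[-1]
        if lb > 50.0:  # exp overflow guard; beta this large is never optimal
            return 1e12
        nll = _nll_core(choices, outcomes, a_pos, a_neg, math.exp(lb), cf, rs, n_arms)
        if not math.isfinite(nll):
            return 1e12
        d = theta - mean
        return nll + 0.5 * float((d * d / var).sum()) + log_norm

    return fun


def _hessian_diag(fun, theta: np.ndarray, step: float = _HESS_STEP) -> np.ndarray:
    f0 = fun(theta)
    h = np.empty_like(theta)
    for i in range(theta.shape[0]):
        e = np.zeros_like(theta)
        e[i] = step
        h[i] = (fun(theta + e) - 2.0 * f0 + fun(theta - e)) / step**2
    return np.maximum(h, _CURV_FLOOR)


def fit_subject_map(
    trials,
    spec: ModelSpec,
    prior: PopulationPrior,
    restarts: int = 10,
    seed: int | np.random.Generator = 0,
    n_arms: int = 3,
    subject: int | None = None,
    warm_start: np.ndarray | None = None,
) -> SubjectFit:
    """MAP fit of one subject under a Gaussian prior in unconstrained space.

    Runs ``restarts`` L-BFGS-B searches (first from the prior mean, optionally
    one from ``warm_start``, the rest from prior draws) and keeps the best.
    Laplace curvature is the central-difference diagonal Hessian of the
    penalized objective at the optimum, floored at a small positive value.
    """
    if prior.dim != spec.n_params:
        raise ParameterError("prior dimension does not match spec")
    choices, outcomes = _trial_arrays(trials)
    if np.unique(choices).size < 2:
        raise InputError("degenerate session: fewer than 2 distinct choices")
    if subject is None:
        subject = int(trials[0].subject)

    rng = np.random.default_rng(seed)
    starts = [prior.mean.copy()]
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float))
    while len(starts) < max(restarts, 1):
        starts.append(prior.sample(rng, 1)[0])
    starts = starts[: max(restarts, 1)]

    fun = _penalized_objective(spec, prior, choices, outcomes, n_arms)
    best = None
    failures = []
    for x0 in starts:
        res = minimize(fun, x0, method="L-BFGS-B")
        if not math.isfinite(res.fun):
            failures.append(str(res.message))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {len(starts)} restarts failed: {failures}")

    theta = np.asarray(best.x, dtype=float)
    params = from_unconstrained(theta, spec)
    nll = negloglik_arrays(params, spec, choices, outcomes, n_arms)
    return SubjectFit(
        subject=subject,
        spec=spec,
        theta=theta,
        params=params,
        nll_map=float(nll),
        objective=float(best.fun),
        hess_diag=_hessian_diag(fun, theta),
        n_trials=len(choices),
        converged=bool(best.success),
    )


def fit_hierarchical_em(
    cohort_trials: dict[int, list],
    spec: ModelSpec,
    max_iter: int = 30,
    tol: float = 1e-3,
    seed: int = 0,
    restarts: int = 10,
    warm_restarts: int = 2,
    n_arms: int = 3,
    init_prior: PopulationPrior | None = None,
) -> CohortFit:
    """Empirical-Bayes EM over a cohort for one model spec.

    E-step: per-subject MAP + Laplace curvature under the current prior
    (multi-start on the first sweep, warm-started afterwards). M-step: prior
    mean <- mean of MAPs; prior variance <- mean of (squared deviation +
    Laplace posterior variance). Iterates until the largest absolute change
    in any prior parameter drops below ``tol``. AIC per subject comes from a
    final refit under the converged prior with variance inflated x100
    (near-flat, so the refit is effectively maximum likelihood).
    """
    if len(cohort_trials) < 5:
        raise InputError(f"need >= 5 subjects, got {len(cohort_trials)}")
    rng = np.random.default_rng(seed)
    prior = init_prior if init_prior is not None else PopulationPrior.default(spec)
    if prior.dim != spec.n_params:
        raise ParameterError("init prior dimension does not match spec")

    subjects = sorted(cohort_trials)
    warm: dict[int, np.ndarray] = {}
    fits: dict[int, SubjectFit] = {}
    log: list[dict] = []
    converged = False
    for it in range(max_iter):
        n_starts = restarts if it == 0 else warm_restarts
        for s in subjects:
            fits[s] = fit_subject_map(
                cohort_trials[s],
                spec,
                prior,
                restarts=n_starts,
                seed=rng.integers(2**32),
                n_arms=n_arms,
                subject=s,
                warm_start=warm.get(s),
            )
            warm[s] = fits[s].theta
        thetas = np.stack([fits[s].theta for s in subjects])
        post_var = np.stack([1.0 / fits[s].hess_diag for s in subjects])
        new_mean = thetas.mean(axis=0)
        new_var = np.maximum(
            ((thetas - new_mean) ** 2 + post_var).mean(axis=0), _VAR_FLOOR
        )
        # negative Laplace log-marginal (up to constants); logged for monotonicity checks
        marginal = float(
            sum(f.objective for f in fits.values())
            + 0.5 * sum(np.log(f.hess_diag).sum() for f in fits.values())
        )
        delta = max(
            np.abs(new_mean - prior.mean).max(), np.abs(new_var - prior.var).max()
        )
        log.append(
            {
                "iter": it,
                "prior_mean": new_mean.tolist(),
                "prior_var": new_var.tolist(),
                "neg_log_marginal": marginal,
                "delta": float(delta),
            }
        )
        prior = PopulationPrior(new_mean, new_var)
        if delta < tol:
            converged = True
            break

    # near-ML refit for AIC under the deflated prior
    flat = prior.deflated(100.0)
    for s in subjects:
        ml = fit_subject_map(
            cohort_trials[s],
            spec,
            flat,
            restarts=2,
            seed=rng.integers(2**32),
            n_arms=n_arms,
            subject=s,
            warm_start=warm[s],
        )
        fits[s].finish_aic(min(ml.nll_map, fits[s].nll_map))

    subject_fits = [fits[s] for s in subjects]
    return CohortFit(
        spec=spec,
        prior=prior,
        subject_fits=subject_fits,
        summed_aic=float(sum(f.aic for f in subject_fits)),
        converged=converged,
        log=log,
    )


def compare_models(fits: list[CohortFit]) -> pd.DataFrame:
    """Rank cohort fits by summed AIC (ties broken toward fewer parameters).

    Returns a table with one row per spec, sorted best-first, with columns
    spec, k, summed_aic, delta_aic, winner.
    """
    if not fits:
        raise InputError("no fits to compare")
    ref = set(fits[0].subjects)
    for f in fits[1:]:
        if set(f.subjects) != ref:
            raise InputError(
                f"subject sets differ between {fits[0].spec.name} and {f.spec.name}"
            )
    df = pd.DataFrame(
        {
            "spec": [f.spec.name for f in fits],
            "k": [f.spec.n_params for f in fits],
            "summed_aic": [f.summed_aic for f in fits],
        }
    ).sort_values(["summed_aic", "k"], kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["summed_aic"] - df["summed_aic"].iloc[0]
    df["winner"] = [i == 0 for i in range(len(df))]
    return df
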