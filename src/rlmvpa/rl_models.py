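"""Rescorla-Wagner model family: updates, softmax policy, likelihood, simulation.

The family is a 2x2 design over two structural flags:

- counterfactual (A+): after each outcome, every unchosen arm is updated
  toward the *inverse* of the received outcome (delta_u = -r - V_u);
- risk-sensitive (RS+): separate learning rates for positive vs negative
  prediction errors.

One update implementation serves both simulation and likelihood evaluation,
so the generative model and the fitted model cannot drift apart. The
likelihood inner loop is numba-jitted when numba is available (pure-Python
fallback otherwise, numerically identical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._errors import InputError, ParameterError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass(frozen=True)
class ModelSpec:
    """Which structural variant of the update rule is in force."""

    counterfactual: bool = False
    risk_sensitive: bool = False

    @property
    def name(self) -> str:
        return ("A+" if self.counterfactual else "A-") + (
            "RS+" if self.risk_sensitive else "RS-"
        )

    @property
    def n_params(self) -> int:
        """Free parameters: (alpha, beta) plus a second rate under RS+."""
        return 3 if self.risk_sensitive else 2

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            cf, rs = {"A+": True, "A-": False}[name[:2]], {"RS+": True, "RS-": False}[name[2:]]
        except (KeyError, IndexError):
            raise ParameterError(f"unknown model spec name {name!r}") from None
        return cls(counterfactual=cf, risk_sensitive=rs)


#: The four legal variants, in conventional order.
MODEL_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec(False, False),
    ModelSpec(True, False),
    ModelSpec(False, True),
    ModelSpec(True, True),
)


@dataclass(frozen=True)
class AgentParams:
    """Learning rates and softmax inverse temperature.

    ``alpha_neg`` is ignored (tied to ``alpha_pos``) under RS- specs.
    """

    alpha_pos: float
    alpha_neg: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_pos <= 1.0) or not (0.0 <= self.alpha_neg <= 1.0):
            raise ParameterError(
                f"learning rates must lie in [0,1]: {self.alpha_pos}, {self.alpha_neg}"
            )
        if not (self.beta >= 0.0):
            raise ParameterError(f"beta must be >= 0, got {self.beta}")


# ---------------------------------------------------------------------------
# parameter transforms (unconstrained fitting space)
# ---------------------------------------------------------------------------

def _logit(x: float) -> float:
    return math.log(x) - math.log1p(-x)


def _expit(x: float) -> float:
    # tanh form is overflow-safe for arbitrarily large |x|
    return 0.5 * (1.0 + math.tanh(0.5 * x))


def to_unconstrained(params: AgentParams, spec: ModelSpec) -> np.ndarray:
    """(alpha..., beta) -> (logit alpha..., log beta); RS- drops alpha_neg."""
    if spec.risk_sensitive:
        return np.array(
            [_logit(params.alpha_pos), _logit(params.alpha_neg), math.log(params.beta)]
        )
    return np.array([_logit(params.alpha_pos), math.log(params.beta)])


def from_unconstrained(theta: np.ndarray, spec: ModelSpec) -> AgentParams:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_params,):
        raise ParameterError(f"theta shape {theta.shape} != ({spec.n_params},)")
    a_pos = _expit(theta[0])
    if spec.risk_sensitive:
        return AgentParams(a_pos, _expit(theta[1]), math.exp(theta[-1]))
    return AgentParams(a_pos, a_pos, math.exp(theta[-1]))


# ---------------------------------------------------------------------------
# core update / likelihood (shared by simulation and fitting)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _update_inplace(V, chosen, r, a_pos, a_neg, counterfactual, risk_sensitive):
    delta = r - V[chosen]
    if delta != 0.0:
        a = a_pos if (delta > 0.0 or not risk_sensitive) else a_neg
        V[chosen] = V[chosen] + a * delta
    if counterfactual:
        for u in range(V.shape[0]):
            if u == chosen:
                continue
            du = -r - V[u]
            if du != 0.0:
                au = a_pos if (du > 0.0 or not risk_sensitive) else a_neg
                V[u] = V[u] + au * du


@njit(cache=True)
def _nll_core(choices, outcomes, a_pos, a_neg, beta, counterfactual, risk_sensitive, n_arms):
    V = np.zeros(n_arms)
    nll = 0.0
    for t in range(choices.shape[0]):
        m = V[0]
        for i in range(1, n_arms):
            if V[i] > m:
                m = V[i]
        z = 0.0
        for i in range(n_arms):
            z += math.exp(beta * (V[i] - m))
        nll -= beta * (V[choices[t]] - m) - math.log(z)
        _update_inplace(V, choices[t], outcomes[t], a_pos, a_neg, counterfactual, risk_sensitive)
    return nll


@njit(cache=True)
def _vseries_core(choices, outcomes, a_pos, a_neg, counterfactual, risk_sensitive, n_arms):
    V = np.zeros(n_arms)
    out = np.empty(choices.shape[0])
    for t in range(choices.shape[0]):
        out[t] = V[choices[t]]
        _update_inplace(V, choices[t], outcomes[t], a_pos, a_neg, counterfactual, risk_sensitive)
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def rw_update(
    V: np.ndarray, chosen: int, r: float, params: AgentParams, spec: ModelSpec
) -> np.ndarray:
    """One Rescorla-Wagner step; returns a new value vector.

    delta = r - V[chosen]; the effective rate is alpha_pos for positive delta
    and (under RS+) alpha_neg for negative delta. Under A+ every unchosen arm
    is additionally updated toward the inverse outcome with the same
    sign-gated rate rule applied to its own prediction error. A zero
    prediction error triggers no update under either rate.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)) or not np.isfinite(r):
        raise ParameterError("non-finite value state or outcome")
    if not (0 <= chosen < V.shape[0]):
        raise IndexError(f"chosen arm {chosen} out of range")
    out = V.copy()
    _update_inplace(
        out, chosen, float(r), params.alpha_pos, params.alpha_neg,
        spec.counterfactual, spec.risk_sensitive,
    )
    return out


def softmax_probs(V: np.ndarray, beta: float) -> np.ndarray:
    """Softmax policy p_i = exp(beta V_i) / sum_j exp(beta V_j), max-stabilized."""
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    V = np.asarray(V, dtype=float)
    x = beta * V
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def _trial_arrays(trials) -> tuple[np.ndarray, np.ndarray]:
    choices = np.array([t.arm for t in trials], dtype=np.int64)
    outcomes = np.array([t.outcome for t in trials], dtype=np.float64)
    idx = np.array([t.trial for t in trials])
    if np.any(np.diff(idx) <= 0):
        raise InputError("trials must be time-ordered within a subject")
    return choices, outcomes


def negloglik(
    params: AgentParams,
    spec: ModelSpec,
    trials,
    n_arms: int = 3,
) -> float:
    """Negative log likelihood of one subject's time-ordered session.

    Values run forward from V = 0; each trial contributes -log p(a_t)
    computed *before* the update for that trial.
    """
    choices, outcomes = _trial_arrays(trials)
    return negloglik_arrays(params, spec, choices, outcomes, n_arms)


def negloglik_arrays(
    params: AgentParams,
    spec: ModelSpec,
    choices: np.ndarray,
    outcomes: np.ndarray,
    n_arms: int = 3,
) -> float:
    """Array fast path of :func:`negloglik` (no ordering check)."""
    return float(
        _nll_core(
            np.asarray(choices, dtype=np.int64),
            np.asarray(outcomes, dtype=np.float64),
            params.alpha_pos, params.alpha_neg, params.beta,
            spec.counterfactual, spec.risk_sensitive, n_arms,
        )
    )


def value_series(
    params: AgentParams,
    spec: ModelSpec,
    trials,
    n_arms: int = 3,
) -> np.ndarray:
    """Expected value of the chosen arm at choice time, per trial.

    Replays the update rule over the subject's observed choice/outcome
    sequence; entry t is V[a_t] *before* trial t's update.
    """
    choices, outcomes = _trial_arrays(trials)
    return np.asarray(
        _vseries_core(
            choices, outcomes,
            params.alpha_pos, params.alpha_neg,
            spec.counterfactual, spec.risk_sensitive, n_arms,
        )
    )


def simulate_agent(params: AgentParams, spec: ModelSpec, config=None, seed=0, subject=0):
    """Generative counterpart of :func:`negloglik`; delegates to the task env."""
    from .task_env import TaskConfig, run_session

    if config is None:
        config = TaskConfig()
    return run_session(params, spec, config=config, seed=seed, subject=subject)
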