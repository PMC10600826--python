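"""Cross-subject reward decoding and choice-phase reactivation scores.

Outcome-phase trial x voxel matrices (row-centered) from all-but-one subject
train a soft-margin SVM with Gaussian kernel; the held-out subject supplies
both the test outcome trials (sensitivity/specificity) and the choice-phase
trials, whose signed decision values ("hyperplane distances") quantify how
strongly the reward pattern is reactivated at choice time. Accuracy is the
mean of sensitivity and specificity.

``loso_decode`` uses a precomputed-Gram fast path (one kernel matrix per
network, sliced per fold); it is numerically equivalent to fitting
:class:`RewardDecoder` per fold, which the test suite verifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from ._errors import InputError, TrainingError
from .synthetic_data import NeuralSession

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecoderConfig:
    """Fixed (not per-fold-tuned) SVM hyperparameters.

    ``gamma=None`` means the conventional reciprocal of (feature count x
    pooled feature variance), computed on the training stack.
    """

    cost: float = 1.0
    gamma: float | None = None
    tol: float = 1e-3
    cache_mb: float = 500.0


@dataclass
class DecodeResult:
    subject: int
    network: int
    sensitivity: float  # true-positive rate on win trials (nan if no wins)
    specificity: float  # true-negative rate on loss trials (nan if no losses)
    accuracy: float  # (sensitivity + specificity) / 2
    distances: np.ndarray  # signed decision values for choice-phase trials


def center_rows(matrix: np.ndarray) -> np.ndarray:
    """Subtract each row's mean (removes per-trial overall activation)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise InputError("expected a non-empty 2-D matrix")
    if matrix.shape[1] < 2:
        raise InputError("need at least 2 voxels to center rows")
    return matrix - matrix.mean(axis=1, keepdims=True)


def _resolve_gamma(X: np.ndarray, config: DecoderConfig) -> float:
    if config.gamma is not None:
        return float(config.gamma)
    v = X.var()
    return 1.0 / (X.shape[1] * v) if v > 0 else 1.0


class RewardDecoder:
    """Gaussian-kernel SVM over row-centered outcome patterns.

    Decision values are signed so that positive means the reward (win) side.
    """

    def __init__(self, config: DecoderConfig = DecoderConfig()):
        self.config = config
        self._svc: SVC | None = None
        self.gamma_: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RewardDecoder":
        X = center_rows(X)
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise TrainingError("training data contain a single outcome class")
        self.gamma_ = _resolve_gamma(X, self.config)
        self._svc = SVC(
            kernel="rbf",
            C=self.config.cost,
            gamma=self.gamma_,
            tol=self.config.tol,
            cache_size=self.config.cache_mb,
        )
        self._svc.fit(X, y)
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise TrainingError("decoder is not fitted")
        return self._svc.decision_function(center_rows(X))


def train_reward_decoder(
    outcome_matrices, labels, config: DecoderConfig = DecoderConfig()
) -> RewardDecoder:
    """Fit a reward decoder on stacked row-centered outcome trials.

    ``outcome_matrices``/``labels`` may be a single (matrix, labels) pair or
    per-subject sequences, which are stacked.
    """
    if isinstance(outcome_matrices, np.ndarray):
        X, y = outcome_matrices, np.asarray(labels)
    else:
        X = np.vstack(list(outcome_matrices))
        y = np.concatenate([np.asarray(l) for l in labels])
    return RewardDecoder(config).fit(X, y)


def _rbf_gram(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """exp(-gamma * squared distances), computed via float32 GEMM for speed."""
    A32, B32 = A.astype(np.float32), B.astype(np.float32)
    G = A32 @ B32.T
    sa = np.einsum("ij,ij->i", A32, A32)
    sb = np.einsum("ij,ij->i", B32, B32)
    K = sa[:, None] + sb[None, :] - 2.0 * G
    np.maximum(K, 0.0, out=K)
    K *= -gamma
    np.exp(K, out=K)
    return K.astype(np.float64)


def _rates(d: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    sens = float(np.mean(d[y == 1] > 0)) if np.any(y == 1) else float("nan")
    spec = float(np.mean(d[y == 0] <= 0)) if np.any(y == 0) else float("nan")
    return sens, spec


def loso_decode(
    sessions: dict[int, NeuralSession],
    config: DecoderConfig = DecoderConfig(),
) -> list[DecodeResult]:
    """Leave-one-subject-out decoding for one network.

    For each held-out subject, an SVM trained on all other subjects'
    row-centered outcome trials is scored on the held-out outcome trials
    (sensitivity / specificity / balanced accuracy) and then applied to the
    held-out row-centered choice trials, yielding signed hyperplane distances
    (positive = reward side). A held-out subject missing one outcome class
    gets ``nan`` for the corresponding rate (logged, excluded from means).
    """
    subjects = sorted(sessions)
    if len(subjects) < 3:
        raise InputError(f"LOSO needs >= 3 subjects, got {len(subjects)}")

    X_blocks, y_blocks, slices = [], [], {}
    start = 0
    for s in subjects:
        sess = sessions[s]
        Xo = center_rows(sess.outcome)
        X_blocks.append(Xo)
        y_blocks.append(sess.win.astype(int))
        slices[s] = slice(start, start + Xo.shape[0])
        start += Xo.shape[0]
    X = np.vstack(X_blocks)
    y = np.concatenate(y_blocks)
    if np.unique(y).size < 2:
        raise TrainingError("cohort outcome labels contain a single class")

    gamma = _resolve_gamma(X, config)
    K = _rbf_gram(X, X, gamma)

    results = []
    idx = np.arange(len(y))
    for s in subjects:
        te = np.zeros(len(y), dtype=bool)
        te[slices[s]] = True
        tr = idx[~te]
        if np.unique(y[tr]).size < 2:
            raise TrainingError(f"training fold for subject {s} is single-class")
        svc = SVC(
            kernel="precomputed",
            C=config.cost,
            tol=config.tol,
            cache_size=config.cache_mb,
        )
        svc.fit(K[np.ix_(tr, tr)], y[tr])

        d_out = svc.decision_function(K[np.ix_(idx[te], tr)])
        sens, spec = _rates(d_out, y[te])
        if np.isnan(sens) or np.isnan(spec):
            log.warning(
                "subject %s has a single outcome class; rate recorded as missing", s
            )
        Xc = center_rows(sessions[s].choice)
        d_choice = svc.decision_function(_rbf_gram(Xc, X[tr], gamma))
        results.append(
            DecodeResult(
                subject=s,
                network=sessions[s].network,
                sensitivity=sens,
                specificity=spec,
                accuracy=(sens + spec) / 2.0,
                distances=np.asarray(d_choice, dtype=float),
            )
        )
    return results


def results_to_frame(results: list[DecodeResult]) -> pd.DataFrame:
    """(subject, network, sensitivity, specificity, accuracy) table."""
    return pd.DataFrame(
        {
            "subject": [r.subject for r in results],
            "network": [r.network for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "specificity": [r.specificity for r in results],
            "accuracy": [r.accuracy for r in results],
        }
    )


def distances_to_frame(results: list[DecodeResult]) -> pd.DataFrame:
    """Long-format (subject, network, trial, distance) table."""
    rows = []
    for r in results:
        for t, d in enumerate(r.distances):
            rows.append((r.subject, r.network, t, d))
    return pd.DataFrame(rows, columns=["subject", "network", "trial", "distance"])


def decoding_report(
    results: list[DecodeResult],
    n_boot: int = 2000,
    seed: int = 0,
    chance: float = 0.5,
) -> pd.DataFrame:
    """Per-network mean accuracy with a bootstrap CI over subjects.

    ``above_chance`` flags networks whose 95% CI lower bound exceeds chance;
    networks at or below chance are therefore left unflagged.
    """
    rng = np.random.default_rng(seed)
    df = results_to_frame(results)
    rows = []
    for network, g in df.groupby("network"):
        acc = g["accuracy"].dropna().to_numpy()
        if acc.size == 0:
            rows.append((network, 0, float("nan"), float("nan"), float("nan"), False))
            continue
        boots = rng.choice(acc, size=(n_boot, acc.size)).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((network, acc.size, acc.mean(), lo, hi, bool(lo > chance)))
    return pd.DataFrame(
        rows,
        columns=["network", "n_subjects", "mean_accuracy", "ci_lo", "ci_hi", "above_chance"],
    )
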