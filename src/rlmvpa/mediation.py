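"""Subject-level coupling index and bootstrap mediation.

The trial-level coupling in the designated striatum network is reduced to one
number per subject — by default the OLS slope of that subject's hyperplane
distances on their expected-value series (a mixed-model BLUP alternative is
available) — and the indirect path symptoms -> coupling -> (log) inverse
temperature is tested by resampling subjects with replacement and reading a
percentile (optionally BCa) confidence interval off the resampled indirect
effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._errors import InputError

log = logging.getLogger(__name__)


def slope_from_series(distances: np.ndarray, v: np.ndarray) -> float:
    """OLS slope of distances on the expected-value series (nan if V constant)."""
    v = np.asarray(v, dtype=float)
    d = np.asarray(distances, dtype=float)
    if v.shape != d.shape:
        raise InputError("distance / V series length mismatch")
    vv = v - v.mean()
    denom = float(vv @ vv)
    if denom == 0.0:
        return float("nan")
    return float(vv @ (d - d.mean()) / denom)


def subject_coupling_slopes(
    table: pd.DataFrame, network: int, method: str = "ols"
) -> pd.Series:
    """Per-subject coupling index for one network.

    ``method="ols"``: independent per-subject slopes. ``method="blup"``:
    best linear unbiased predictors of subject slopes from a random-slope
    mixed model (shrunken toward the fixed effect). Subjects with fewer than
    10 trials or a constant V series come back as ``nan`` (logged).
    """
    df = table[table["network"] == network]
    if df.empty:
        raise InputError(f"no rows for network {network}")
    if method == "blup":
        return _blup_slopes(df)
    if method != "ols":
        raise InputError(f"unknown method {method!r}")
    out = {}
    for s, g in df.groupby("subject"):
        if len(g) < 10:
            log.warning("subject %s: only %d trials; slope undefined", s, len(g))
            out[s] = float("nan")
            continue
        slope = slope_from_series(g["distance"].to_numpy(), g["V"].to_numpy())
        if np.isnan(slope):
            log.warning("subject %s: zero-variance V; slope undefined", s)
        out[s] = slope
    return pd.Series(out, name="coupling_slope").rename_axis("subject")


def _blup_slopes(df: pd.DataFrame) -> pd.Series:
    import statsmodels.formula.api as smf

    md = smf.mixedlm("distance ~ V", df, groups="subject", re_formula="~V")
    res = md.fit(reml=True)
    fixed = float(res.fe_params["V"])
    out = {
        s: fixed + float(re.get("V", 0.0)) for s, re in res.random_effects.items()
    }
    return pd.Series(out, name="coupling_slope").rename_axis("subject")


@dataclass
class MediationResult:
    a: float  # X -> M
    b: float  # M -> Y | X
    c: float  # total X -> Y
    c_prime: float  # direct X -> Y | M
    ab: float  # indirect effect
    ci: tuple[float, float]
    ci_level: float
    p: float
    n_boot: int
    seed: int
    n: int
    method: str
    boot_mean: float
    boot_sd: float
    n_redraws: int = 0
    covariate_names: list = field(default_factory=list)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "a", "b", "c", "c_prime", "ab", "ci_level", "p", "n_boot",
            "seed", "n", "method", "boot_mean", "boot_sd", "n_redraws",
            "covariate_names",
        )}
        d["ci"] = list(self.ci)
        return json.dumps(d, indent=1)

    def text_report(self) -> str:
        lo, hi = self.ci
        lines = [
            "Mediation analysis (subject-resampling bootstrap)",
            "-" * 49,
            f"n subjects (complete cases): {self.n}",
            f"covariates: {', '.join(self.covariate_names) or 'none'}",
            f"path a  (X -> M):          {self.a:+.4f}",
            f"path b  (M -> Y | X):      {self.b:+.4f}",
            f"path c  (total X -> Y):    {self.c:+.4f}",
            f"path c' (direct X -> Y):   {self.c_prime:+.4f}",
            f"indirect effect ab:        {self.ab:+.4f}",
            f"{self.ci_level:.0%} {self.method} CI: [{lo:+.4f}, {hi:+.4f}]",
            f"two-sided bootstrap p:     {self.p:.4g}",
            f"bootstrap iterations:      {self.n_boot} (seed {self.seed}, "
            f"{self.n_redraws} degenerate resamples redrawn)",
        ]
        return "\n".join(lines)


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def mediation_bootstrap(
    X,
    M,
    Y,
    covariates=None,
    n_boot: int = 50_000,
    seed: int = 0,
    ci_level: float = 0.95,
    method: str = "percentile",
) -> MediationResult:
    """Percentile-bootstrap test of the indirect effect a*b.

    Point estimates come from two least-squares fits on the full sample
    (M ~ X + C gives a; Y ~ X + M + C gives b and c'; Y ~ X + C gives c, and
    c = c' + a*b holds exactly). Each bootstrap resample redraws subjects
    with replacement, refits both regressions, and records a*b; degenerate
    resamples (constant X or M) are redrawn and counted. The two-sided p is
    2 * min(Pr(ab <= 0), Pr(ab >= 0)) over the bootstrap distribution, ties
    counted on both sides (hence p can exceed 1 only before capping at 1).
    ``method="bca"`` applies the bias-corrected-and-accelerated adjustment to
    the percentile endpoints.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if covariates is None:
        C = np.empty((len(X), 0))
        cov_names: list[str] = []
    else:
        if isinstance(covariates, pd.DataFrame):
            cov_names = list(covariates.columns)
            C = covariates.to_numpy(dtype=float)
        else:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != len(X):
                C = C.T
            cov_names = [f"c{i}" for i in range(C.shape[1])]
    if method not in ("percentile", "bca"):
        raise InputError(f"unknown CI method {method!r}")

    keep = np.isfinite(X) & np.isfinite(M) & np.isfinite(Y) & np.all(np.isfinite(C), axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d incomplete cases", n_drop)
    X, M, Y, C = X[keep], M[keep], Y[keep], C[keep]
    n = len(X)
    if n < 20:
        raise InputError(f"need >= 20 complete cases, got {n}")

    ones = np.ones((n, 1))

    def paths(x, m, y, c):
        o = np.ones((len(x), 1))
        za = np.hstack([o, x[:, None], c])
        a = _ols_coef(za, m)[1]
        zb = np.hstack([o, x[:, None], m[:, None], c])
        cb = _ols_coef(zb, y)
        return a, cb[2], cb[1]  # a, b, c_prime

    a, b, c_prime = paths(X, M, Y, C)
    c = _ols_coef(np.hstack([ones, X[:, None], C]), Y)[1]
    ab = a * b

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n_redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(n, size=n)
            if np.ptp(X[idx]) > 0 and np.ptp(M[idx]) > 0:
                break
            n_redraws += 1
        a_i, b_i, _ = paths(X[idx], M[idx], Y[idx], C[idx])
        boots[i] = a_i * b_i

    alpha = 1.0 - ci_level
    if method == "percentile":
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:  # BCa
        z0 = norm.ppf(np.clip(np.mean(boots < ab), 1e-9, 1 - 1e-9))
        jack = np.empty(n)
        for i in range(n):
            idx = np.delete(np.arange(n), i)
            a_i, b_i, _ = paths(X[idx], M[idx], Y[idx], C[idx])
            jack[i] = a_i * b_i
        jm = jack.mean()
        num = np.sum((jm - jack) ** 3)
        den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
        acc = num / den if den > 0 else 0.0
        zlo, zhi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
        plo = norm.cdf(z0 + (z0 + zlo) / (1 - acc * (z0 + zlo)))
        phi = norm.cdf(z0 + (z0 + zhi) / (1 - acc * (z0 + zhi)))
        lo, hi = np.percentile(boots, [100 * plo, 100 * phi])

    p = min(1.0, 2.0 * min(np.mean(boots <= 0.0), np.mean(boots >= 0.0)))
    return MediationResult(
        a=float(a),
        b=float(b),
        c=float(c),
        c_prime=float(c_prime),
        ab=float(ab),
        ci=(float(lo), float(hi)),
        ci_level=ci_level,
        p=float(p),
        n_boot=n_boot,
        seed=seed,
        n=n,
        method=method,
        boot_mean=float(boots.mean()),
        boot_sd=float(boots.std(ddof=1)),
        n_redraws=n_redraws,
        covariate_names=cov_names,
    )
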