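"""Trial-level mixed-effects coupling between expected value and reactivation
distances, moderation by subject-level variables, and Bonferroni control.

The unit of analysis is the trial: for each network, hyperplane distances are
regressed on the fitted model's expected value of the chosen arm with age,
IQ, head motion and the subject's own decoding accuracy as covariates, and
random intercepts for site and subject-within-site (REML; fixed-effect tests
by the large-sample normal approximation). Moderation models add a
subject-level moderator and its interaction with expected value; clinical
moderators retain log trauma severity as a covariate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from ._errors import DegenerateDesignError, InputError
from .rl_models import value_series

log = logging.getLogger(__name__)

#: moderators that are clinical scales (log-CTQ retained as covariate)
CLINICAL_MODERATORS = frozenset({"internalizing", "depression", "anxiety", "somatic"})

#: trial-level / subject-level continuous columns standardized cohort-wide
STANDARDIZED_COLUMNS = (
    "V",
    "age",
    "iq",
    "motion",
    "acc",
    "log_beta",
    "log_ctq",
    "internalizing",
    "depression",
    "anxiety",
    "somatic",
)

BASE_FORMULA = "distance ~ V + age + iq + motion + acc"


@dataclass
class CouplingFit:
    network: int
    formula: str
    terms: pd.DataFrame  # term, estimate, se, stat, p
    re_var: dict[str, float]
    n_obs: int
    converged: bool
    random_structure: str  # "site/subject" or "subject"

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"term {name!r} not in model {self.formula!r}")
        return row.iloc[0]


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x * 0.0


def assemble_trial_table(
    subject_fits: dict[int, "object"],
    decode_results: list,
    covariates: pd.DataFrame,
    trial_records: dict[int, list],
) -> pd.DataFrame:
    """Join fitted values, distances, and covariates into the long trial table.

    The expected-value series is regenerated by replaying each subject's
    *fitted* parameters over their observed choice/outcome sequence (never
    the generating parameters). Continuous predictors are standardized
    cohort-wide after the join. Subjects missing decode output are dropped
    with a logged reason; unknown subjects in the decode results are errors.
    """
    cov = covariates.set_index("subject")
    known = set(cov.index) & set(subject_fits) & set(trial_records)
    offenders = sorted({r.subject for r in decode_results} - known)
    if offenders:
        raise InputError(f"decode results reference unknown subjects: {offenders}")

    decoded = {r.subject for r in decode_results}
    for s in sorted(known - decoded):
        log.info("subject %s has no decode output; excluded from trial table", s)

    v_cache: dict[int, np.ndarray] = {}
    rows = []
    for r in decode_results:
        s = r.subject
        fit = subject_fits[s]
        if s not in v_cache:
            v_cache[s] = value_series(fit.params, fit.spec, trial_records[s])
        v = v_cache[s]
        if len(v) != len(r.distances):
            raise InputError(
                f"subject {s}: {len(r.distances)} distances vs {len(v)} trials"
            )
        c = cov.loc[s]
        for t in range(len(v)):
            rows.append(
                (
                    s, int(c["site"]), r.network, t, r.distances[t], v[t],
                    c["age"], c["iq"], c["motion"], r.accuracy,
                    float(np.log(fit.params.beta)), c["log_ctq"],
                    c["internalizing"], c["depression"], c["anxiety"], c["somatic"],
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "subject", "site", "network", "trial", "distance", "V",
            "age", "iq", "motion", "acc", "log_beta", "log_ctq",
            "internalizing", "depression", "anxiety", "somatic",
        ],
    )
    for col in STANDARDIZED_COLUMNS:
        table[col] = _zscore(table[col])
    return table


def _extract(res, formula, network, n_obs, structure, converged) -> CouplingFit:
    fe = res.fe_params
    terms = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.to_numpy(),
            "se": res.bse_fe.to_numpy(),
            "stat": (fe / res.bse_fe).to_numpy(),
            "p": res.pvalues[fe.index].to_numpy(),
        }
    )
    re_var = {}
    try:
        re_var = {k: float(v) for k, v in res.vcomp_named.items()}
    except AttributeError:
        if res.model.k_vc:
            re_var = {
                name: float(v)
                for name, v in zip(res.model.exog_vc.names, res.vcomp)
            }
    re_var["group_intercept"] = float(np.atleast_2d(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    return CouplingFit(
        network=network,
        formula=formula,
        terms=terms,
        re_var=re_var,
        n_obs=n_obs,
        converged=converged,
        random_structure=structure,
    )


def _fit_lmem(df: pd.DataFrame, formula: str, network: int) -> CouplingFit:
    """REML mixed model with site + subject-within-site random intercepts.

    Falls back to a subject-only random intercept (flagged via
    ``random_structure``) if the nested fit fails or does not converge.
    """
    n_sites = df["site"].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        if n_sites >= 2:
            try:
                md = smf.mixedlm(
                    formula,
                    df,
                    groups="site",
                    re_formula="1",
                    vc_formula={"subject": "0 + C(subject)"},
                )
                res = md.fit(reml=True)
                if res.converged:
                    return _extract(res, formula, network, len(df), "site/subject", True)
                log.warning("network %s: nested LMEM did not converge; refitting subject-only", network)
            except (np.linalg.LinAlgError, ValueError) as e:
                log.warning("network %s: nested LMEM failed (%s); refitting subject-only", network, e)
        md = smf.mixedlm(formula, df, groups="subject", re_formula="1")
        res = md.fit(reml=True)
    return _extract(res, formula, network, len(df), "subject", bool(res.converged))


def fit_coupling_lmem(table: pd.DataFrame, network: int) -> CouplingFit:
    """distance ~ V + age + iq + motion + acc with nested random intercepts."""
    df = table[table["network"] == network]
    if df["subject"].nunique() < 10:
        raise InputError("coupling model needs >= 10 subjects")
    return _fit_lmem(df.copy(), BASE_FORMULA, network)


def fit_moderation_lmem(
    table: pd.DataFrame, network: int, moderator: str
) -> CouplingFit:
    """Coupling model plus moderator main effect and V x moderator interaction.

    Clinical moderators (CBCL scales) additionally retain log-CTQ as a
    covariate. A constant moderator makes the interaction inestimable and is
    rejected outright.
    """
    if moderator not in table.columns:
        raise InputError(f"moderator column {moderator!r} not in table")
    df = table[table["network"] == network].copy()
    if df["subject"].nunique() < 10:
        raise InputError("moderation model needs >= 10 subjects")
    if df[moderator].std(ddof=0) == 0:
        raise DegenerateDesignError(
            f"moderator {moderator!r} is constant; interaction inestimable"
        )
    formula = BASE_FORMULA + f" + {moderator} + V:{moderator}"
    if moderator in CLINICAL_MODERATORS:
        formula += " + log_ctq"
    return _fit_lmem(df, formula, network)


def bonferroni_adjust(
    pvalues, m: int, family_alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Family-wise corrected alpha (family_alpha / m) and below-threshold flags."""
    if m < 1:
        raise InputError(f"m must be >= 1, got {m}")
    corrected = family_alpha / m
    p = np.asarray(pvalues, dtype=float)
    return corrected, p < corrected


def coupling_results_to_frame(
    fits: list[CouplingFit],
    flag_term: str | None = None,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Stack model terms across networks; optionally Bonferroni-flag one term.

    The correction family size is the number of networks tested.
    """
    frames = []
    for f in fits:
        t = f.terms.copy()
        t.insert(0, "network", f.network)
        t["converged"] = f.converged
        t["random_structure"] = f.random_structure
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out["flagged"] = False
    if flag_term is not None:
        mask = out["term"] == flag_term
        corrected, flags = bonferroni_adjust(
            out.loc[mask, "p"].to_numpy(), m=len(fits), family_alpha=family_alpha
        )
        out.loc[mask, "flagged"] = flags
        out.attrs["bonferroni_alpha"] = corrected
    return out
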