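"""Synthetic cohort generator: covariates, bandit behavior, and per-network
trial x voxel pattern matrices with planted, configurable effect structure.

The generator plants exactly the statistical structure the downstream
analyses assume, with every magnitude exposed in :class:`CohortConfig`:

- a latent symptom factor S drives the caregiver-rated symptom scales and is
  moderately correlated with (log) trauma severity;
- softmax inverse temperatures follow ``log beta = b0 + b1 * z(S) + eps``
  with ``b1 < 0`` by default (more symptoms -> more choice stochasticity);
- each network carries one fixed unit-norm pattern direction shared across
  subjects; outcome-phase rows encode win/loss along it at a configurable
  SNR; choice-phase rows encode ``kappa_i * V_chosen(t)`` along it, where the
  subject-level coupling strength ``kappa_i`` declines with z(S) in the one
  designated "striatum" network only (``k1 < 0`` there, 0 elsewhere);
- per-subject noise level rises weakly with the head-motion covariate so the
  motion nuisance regressor has a real job.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigError, InputError
from .rl_models import AgentParams, ModelSpec, value_series
from .task_env import TaskConfig, run_session, trials_to_frame


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort; no hidden constants."""

    n_subjects: int = 60
    n_sites: int = 2
    n_networks: int = 8
    striatum_network_index: int = 0
    n_voxels: int = 200
    task: TaskConfig = field(default_factory=TaskConfig)

    # neural signal structure
    outcome_snr: float = 2.0  # outcome-phase signal amplitude along the pattern
    k0: float = 1.0  # baseline choice-phase coupling strength
    k1: float = -0.4  # symptom slope of coupling, striatum network only
    coupling_noise_sd: float = 0.2  # subject-level jitter eta on kappa
    noise_sd: float = 1.0  # voxel noise scale
    motion_noise_coef: float = 0.1  # how strongly motion inflates noise

    # behavior-generating population
    gen_spec: ModelSpec = field(default_factory=lambda: ModelSpec(True, True))
    beta_intercept: float = float(np.log(4.0))  # b0 on the log-beta scale
    beta_slope: float = -0.5  # b1: symptom slope of log beta
    beta_noise_sd: float = 0.3
    # clearly distinct rates so the RS+ structure is identifiable at 90 trials
    alpha_pos_mean: float = 0.4  # logit scale (~0.60)
    alpha_neg_mean: float = -2.0  # logit scale (~0.12)
    alpha_sd: float = 0.4

    # covariates
    age_mean: float = 15.0
    age_sd: float = 1.5
    iq_mean: float = 105.0
    iq_sd: float = 12.0
    motion_log_mean: float = -1.5
    motion_log_sd: float = 0.5
    ctq_log_mean: float = 3.5
    ctq_s_loading: float = 0.35
    ctq_log_noise_sd: float = 0.6
    cbcl_mean: float = 55.0
    cbcl_scale: float = 10.0
    cbcl_loading: float = 0.9
    cbcl_noise_sd: float = 0.44
    subscale_loading: float = 0.8
    subscale_noise_sd: float = 0.6

    def __post_init__(self) -> None:
        if not (0 <= self.striatum_network_index < self.n_networks):
            raise ConfigError("striatum_network_index out of range")
        if self.outcome_snr <= 0:
            raise ConfigError("outcome SNR must be positive")
        if self.n_subjects < 1 or self.n_networks < 1 or self.n_voxels < 2:
            raise ConfigError("cohort dimensions must be positive (>= 2 voxels)")


@dataclass(frozen=True)
class SubjectCovariates:
    subject: int
    site: int
    age: float
    iq: float
    motion: float
    ctq_total: float
    log_ctq: float
    internalizing: float
    depression: float
    anxiety: float
    somatic: float
    latent_s: float


@dataclass
class NeuralSession:
    """Outcome- and choice-phase pattern matrices for one subject x network."""

    subject: int
    network: int
    outcome: np.ndarray  # (n_trials, n_voxels)
    choice: np.ndarray  # (n_trials, n_voxels)
    win: np.ndarray  # bool labels per trial
    kappa: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.outcome.shape != self.choice.shape:
            raise InputError("outcome/choice shape mismatch")
        if self.outcome.shape[0] != self.win.shape[0]:
            raise InputError("label count does not match trial count")
        if not (np.all(np.isfinite(self.outcome)) and np.all(np.isfinite(self.choice))):
            raise InputError("non-finite pattern matrix")


def sample_covariates(config: CohortConfig, seed) -> pd.DataFrame:
    """Draw the subject covariate table (one row per subject).

    Site assignment is round-robin (counts differ by at most one). The latent
    factor S feeds the CBCL scales through configurable loadings and log-CTQ
    through a weaker loading, so trauma severity correlates with symptoms but
    carries no independent link to the planted neural coupling.
    """
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    s = rng.normal(size=n)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    iq = rng.normal(config.iq_mean, config.iq_sd, size=n)
    motion = np.exp(rng.normal(config.motion_log_mean, config.motion_log_sd, size=n))
    log_ctq = (
        config.ctq_log_mean
        + config.ctq_s_loading * s
        + rng.normal(0, config.ctq_log_noise_sd, size=n)
    )

    def scale(loading, noise_sd):
        return config.cbcl_mean + config.cbcl_scale * (
            loading * s + noise_sd * rng.normal(size=n)
        )

    df = pd.DataFrame(
        {
            "subject": np.arange(n),
            "site": np.arange(n) % config.n_sites,
            "age": age,
            "iq": iq,
            "motion": motion,
            "ctq_total": np.exp(log_ctq),
            "log_ctq": log_ctq,
            "internalizing": scale(config.cbcl_loading, config.cbcl_noise_sd),
            "depression": scale(config.subscale_loading, config.subscale_noise_sd),
            "anxiety": scale(config.subscale_loading, config.subscale_noise_sd),
            "somatic": scale(config.subscale_loading, config.subscale_noise_sd),
            "latent_s": s,
        }
    )
    return df


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def sample_agent_params(
    covariates: pd.DataFrame, config: CohortConfig, seed
) -> dict[int, AgentParams]:
    """Per-subject RW parameters: log beta declines with the symptom factor.

    ``log beta_i = b0 + b1 * z(S_i) + eps``; learning rates are Gaussian in
    logit space and independent of S.
    """
    rng = np.random.default_rng(seed)
    n = len(covariates)
    z_s = _zscore(covariates["latent_s"].to_numpy())
    log_beta = (
        config.beta_intercept
        + config.beta_slope * z_s
        + rng.normal(0, config.beta_noise_sd, size=n)
    )
    lp = rng.normal(config.alpha_pos_mean, config.alpha_sd, size=n)
    ln = rng.normal(config.alpha_neg_mean, config.alpha_sd, size=n)
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
    return {
        int(sid): AgentParams(float(expit(lp[i])), float(expit(ln[i])), float(np.exp(log_beta[i])))
        for i, sid in enumerate(covariates["subject"])
    }


def network_patterns(config: CohortConfig, seed) -> np.ndarray:
    """Fixed unit-norm pattern direction per network, shared across subjects."""
    rng = np.random.default_rng(seed)
    w = rng.normal(size=(config.n_networks, config.n_voxels))
    return w / np.linalg.norm(w, axis=1, keepdims=True)


def subject_noise_sd(motion: float, config: CohortConfig) -> float:
    """Noise level weakly increasing with (log) head motion, floored at half base."""
    dev = np.log(motion) - config.motion_log_mean
    return float(max(config.noise_sd * (1.0 + config.motion_noise_coef * dev), 0.5 * config.noise_sd))


def generate_neural_session(
    trials,
    v_series: np.ndarray,
    covariates: SubjectCovariates,
    z_s: float,
    network: int,
    config: CohortConfig,
    seed,
    pattern: np.ndarray | None = None,
) -> NeuralSession:
    """Generate one subject x network pattern pair.

    Outcome rows: ``snr * z_r * w + noise`` with ``z_r`` the +/-1 outcome
    coding. Choice rows: ``kappa * V_chosen(t) * w + noise`` where ``kappa =
    k0 + k1 * z(S) + eta`` in the striatum network and ``k0 + eta`` elsewhere.
    ``v_series`` must be the generating agent's own chosen-arm values.
    """
    v_series = np.asarray(v_series, dtype=float)
    if len(v_series) != len(trials):
        raise InputError(
            f"V-series length {len(v_series)} != trial count {len(trials)}"
        )
    rng = np.random.default_rng(seed)
    if pattern is None:
        pattern = network_patterns(config, seed)[network]
    w = np.asarray(pattern, dtype=float)

    k1 = config.k1 if network == config.striatum_network_index else 0.0
    kappa = config.k0 + k1 * z_s + rng.normal(0, config.coupling_noise_sd)
    sd = subject_noise_sd(covariates.motion, config)

    z_r = np.array([t.outcome for t in trials], dtype=float)
    win = np.array([t.win for t in trials], dtype=bool)
    n_t, n_v = len(trials), config.n_voxels
    outcome = config.outcome_snr * z_r[:, None] * w[None, :] + sd * rng.normal(size=(n_t, n_v))
    choice = kappa * v_series[:, None] * w[None, :] + sd * rng.normal(size=(n_t, n_v))
    return NeuralSession(
        subject=covariates.subject,
        network=network,
        outcome=outcome,
        choice=choice,
        win=win,
        kappa=float(kappa),
        noise_sd=sd,
    )


@dataclass
class Cohort:
    """Everything downstream stages consume, plus generation bookkeeping."""

    config: CohortConfig
    seed: int
    covariates: pd.DataFrame  # includes cohort-standardized z_s column
    trials: pd.DataFrame
    trial_records: dict[int, list]
    agent_params: dict[int, AgentParams]
    v_series: dict[int, np.ndarray]
    patterns: np.ndarray  # (n_networks, n_voxels)
    sessions: dict[tuple[int, int], NeuralSession]  # (subject, network) -> session
    manifest: dict

    @property
    def subjects(self) -> list[int]:
        return sorted(self.trial_records)

    def network_sessions(self, network: int) -> dict[int, NeuralSession]:
        return {s: self.sessions[(s, network)] for s in self.subjects}

    def save(self, outdir: str | Path) -> None:
        """Write covariates/trials/params as CSV, patterns as .npy + JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        pd.DataFrame(
            {
                "subject": self.subjects,
                "alpha_pos": [self.agent_params[s].alpha_pos for s in self.subjects],
                "alpha_neg": [self.agent_params[s].alpha_neg for s in self.subjects],
                "beta": [self.agent_params[s].beta for s in self.subjects],
            }
        ).to_csv(outdir / "agent_params.csv", index=False)
        subs, nets = self.subjects, range(self.config.n_networks)
        t_cfg = self.config.task
        out4 = np.stack(
            [np.stack([self.sessions[(s, n)].outcome for n in nets]) for s in subs]
        )
        cho4 = np.stack(
            [np.stack([self.sessions[(s, n)].choice for n in nets]) for s in subs]
        )
        np.save(outdir / "outcome_patterns.npy", out4)
        np.save(outdir / "choice_patterns.npy", cho4)
        np.save(outdir / "network_patterns.npy", self.patterns)
        kappas = {f"{s}:{n}": self.sessions[(s, n)].kappa for s in subs for n in nets}
        sidecar = {
            "axes": ["subject", "network", "trial", "voxel"],
            "subjects": subs,
            "n_networks": self.config.n_networks,
            "n_trials": t_cfg.n_trials,
            "n_voxels": self.config.n_voxels,
            "dtype": "float64",
            "kappa": kappas,
            "seed": self.seed,
        }
        (outdir / "neural_meta.json").write_text(json.dumps(sidecar, indent=1))
        (outdir / "cohort_manifest.json").write_text(json.dumps(self.manifest, indent=1))

    def to_long_csv(self, path: str | Path, max_cells: int = 2_000_000) -> None:
        """Export all pattern matrices as one long CSV (small cohorts only).

        Columns: subject, network, phase, trial, voxel, value. Refuses to
        write more than ``max_cells`` rows.
        """
        n_cells = (
            len(self.subjects)
            * self.config.n_networks
            * self.config.task.n_trials
            * self.config.n_voxels
            * 2
        )
        if n_cells > max_cells:
            raise InputError(
                f"cohort has {n_cells} cells; long CSV capped at {max_cells}"
            )
        frames = []
        for (s, n), sess in sorted(self.sessions.items()):
            for phase, mat in (("outcome", sess.outcome), ("choice", sess.choice)):
                t_idx, v_idx = np.unravel_index(np.arange(mat.size), mat.shape)
                frames.append(
                    pd.DataFrame(
                        {
                            "subject": s,
                            "network": n,
                            "phase": phase,
                            "trial": t_idx,
                            "voxel": v_idx,
                            "value": mat.ravel(),
                        }
                    )
                )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def load(cls, outdir: str | Path) -> "Cohort":
        from .task_env import frame_to_trials

        outdir = Path(outdir)
        manifest = json.loads((outdir / "cohort_manifest.json").read_text())
        config = config_from_dict(manifest["config"])
        covariates = pd.read_csv(outdir / "covariates.csv")
        trials = pd.read_csv(outdir / "trials.csv")
        params_df = pd.read_csv(outdir / "agent_params.csv")
        agent_params = {
            int(r.subject): AgentParams(r.alpha_pos, r.alpha_neg, r.beta)
            for r in params_df.itertuples(index=False)
        }
        sidecar = json.loads((outdir / "neural_meta.json").read_text())
        out4 = np.load(outdir / "outcome_patterns.npy")
        cho4 = np.load(outdir / "choice_patterns.npy")
        patterns = np.load(outdir / "network_patterns.npy")
        trial_records = {
            int(s): frame_to_trials(g.sort_values("trial"))
            for s, g in trials.groupby("subject")
        }
        v_series = {
            s: value_series(agent_params[s], config.gen_spec, recs)
            for s, recs in trial_records.items()
        }
        sessions = {}
        for i, s in enumerate(sidecar["subjects"]):
            win = np.array([t.win for t in trial_records[s]], dtype=bool)
            for n in range(sidecar["n_networks"]):
                sessions[(s, n)] = NeuralSession(
                    subject=s,
                    network=n,
                    outcome=out4[i, n],
                    choice=cho4[i, n],
                    win=win,
                    kappa=sidecar["kappa"][f"{s}:{n}"],
                    noise_sd=float("nan"),
                )
        return cls(
            config=config,
            seed=manifest["seed"],
            covariates=covariates,
            trials=trials,
            trial_records=trial_records,
            agent_params=agent_params,
            v_series=v_series,
            patterns=patterns,
            sessions=sessions,
            manifest=manifest,
        )


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["task"] = dataclasses.asdict(config.task)
    d["gen_spec"] = config.gen_spec.name
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    task = d.pop("task", {})
    if isinstance(task, dict):
        for key in ("prob_set", "outcome_coding"):
            if key in task and task[key] is not None:
                task[key] = tuple(task[key])
        task = TaskConfig(**task)
    spec = d.pop("gen_spec", "A+RS+")
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    return CohortConfig(task=task, gen_spec=spec, **d)


def generate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Generate a complete cohort: covariates, behavior, and all pattern matrices.

    All randomness descends from named child streams of ``seed`` (covariates,
    agent parameters, behavior, network patterns, one stream per subject x
    network session); the manifest records the derivation so any piece can be
    regenerated in isolation. Bit-reproducible for a fixed (config, seed).
    """
    root = np.random.SeedSequence(seed)
    cov_ss, par_ss, beh_ss, pat_ss, neu_ss = root.spawn(5)

    covariates = sample_covariates(config, cov_ss)
    covariates["z_s"] = _zscore(covariates["latent_s"].to_numpy())
    agent_params = sample_agent_params(covariates, config, par_ss)

    beh_children = beh_ss.spawn(config.n_subjects)
    trial_records: dict[int, list] = {}
    v_series: dict[int, np.ndarray] = {}
    for i, sid in enumerate(int(s) for s in covariates["subject"]):
        recs = run_session(
            agent_params[sid],
            config.gen_spec,
            config=config.task,
            seed=beh_children[i],
            subject=sid,
        )
        trial_records[sid] = recs
        v_series[sid] = value_series(agent_params[sid], config.gen_spec, recs)

    patterns = network_patterns(config, pat_ss)
    neu_children = neu_ss.spawn(config.n_subjects * config.n_networks)
    sessions: dict[tuple[int, int], NeuralSession] = {}
    cov_rows = {
        int(r.subject): SubjectCovariates(
            subject=int(r.subject), site=int(r.site), age=r.age, iq=r.iq,
            motion=r.motion, ctq_total=r.ctq_total, log_ctq=r.log_ctq,
            internalizing=r.internalizing, depression=r.depression,
            anxiety=r.anxiety, somatic=r.somatic, latent_s=r.latent_s,
        )
        for r in covariates.itertuples(index=False)
    }
    z_s = dict(zip(covariates["subject"].astype(int), covariates["z_s"]))
    for i, sid in enumerate(sorted(trial_records)):
        for n in range(config.n_networks):
            sessions[(sid, n)] = generate_neural_session(
                trial_records[sid],
                v_series[sid],
                cov_rows[sid],
                z_s[sid],
                n,
                config,
                neu_children[i * config.n_networks + n],
                pattern=patterns[n],
            )

    manifest = {
        "seed": seed,
        "config": config_to_dict(config),
        "seed_streams": {
            "covariates": str(cov_ss.spawn_key),
            "agent_params": str(par_ss.spawn_key),
            "behavior": str(beh_ss.spawn_key),
            "patterns": str(pat_ss.spawn_key),
            "neural": str(neu_ss.spawn_key),
        },
        "n_subjects": config.n_subjects,
        "n_networks": config.n_networks,
    }
    trials = pd.concat(
        [trials_to_frame(trial_records[s]) for s in sorted(trial_records)],
        ignore_index=True,
    )
    return Cohort(
        config=config,
        seed=seed,
        covariates=covariates,
        trials=trials,
        trial_records=trial_records,
        agent_params=agent_params,
        v_series=v_series,
        patterns=patterns,
        sessions=sessions,
        manifest=manifest,
    )
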