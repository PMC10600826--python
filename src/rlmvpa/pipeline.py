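"""Pipeline orchestration: simulate -> fit -> decode -> couple -> mediate -> report.

Each stage communicates with the next only through serialized files inside
the run directory, so stages can be re-run (or run in separate processes)
independently. A manifest records the config snapshot, the per-stage seed
derivation, wall times, and a checksum for every file written; re-running
with the same master seed reproduces the checksums bit-for-bit.

Stage seeds derive from the master seed by spawn key: stage ``i`` in
:data:`STAGES` uses ``numpy.random.SeedSequence(master_seed, spawn_key=(i,))``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigError
from .coupling import (
    CLINICAL_MODERATORS,
    assemble_trial_table,
    bonferroni_adjust,
    coupling_results_to_frame,
    fit_coupling_lmem,
    fit_moderation_lmem,
)
from .mediation import mediation_bootstrap, subject_coupling_slopes
from .model_fitting import CohortFit, compare_models, fit_hierarchical_em
from .mvpa import (
    DecodeResult,
    DecoderConfig,
    decoding_report,
    distances_to_frame,
    loso_decode,
    results_to_frame,
)
from .rl_models import MODEL_SPECS, AgentParams, ModelSpec
from .synthetic_data import Cohort, CohortConfig, config_from_dict, config_to_dict, generate_cohort
from .task_env import frame_to_trials

log = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "decode", "couple", "mediate", "report")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.00625 -> 0.0063 at 4 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML round-trippable."""

    seed: int = 1
    outdir: str = "runs/default"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    fit_specs: tuple[str, ...] = tuple(s.name for s in MODEL_SPECS)
    fit_restarts: int = 10
    fit_warm_restarts: int = 2
    fit_max_iter: int = 30
    fit_tol: float = 1e-3
    moderators: tuple[str, ...] = ("log_beta", "internalizing")
    mediation_symptoms: tuple[str, ...] = ("internalizing",)
    mediation_n_boot: int = 50_000
    family_alpha: float = 0.05
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages in config: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        for name in self.fit_specs:
            ModelSpec.from_name(name)  # validates

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = config_to_dict(self.cohort)
        d["decoder"] = dataclasses.asdict(self.decoder)
        d["fit_specs"] = list(self.fit_specs)
        d["moderators"] = list(self.moderators)
        d["mediation_symptoms"] = list(self.mediation_symptoms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = config_from_dict(d["cohort"])
        if "decoder" in d:
            d["decoder"] = DecoderConfig(**d["decoder"])
        for key in ("fit_specs", "moderators", "mediation_symptoms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Named, documented per-stage seed stream (see module docstring)."""
    return np.random.SeedSequence(master_seed, spawn_key=(STAGES.index(stage),))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.path = outdir / "run_manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "version": __version__,
                "config": config.to_dict(),
                "stage_seed_rule": "SeedSequence(master_seed, spawn_key=(stage_index,))",
                "stages": {},
                "checksums": {},
            }

    def record(self, stage: str, outdir: Path, files: list[Path], wall: float, **info):
        self.data["stages"][stage] = {"wall_seconds": wall, **info}
        for f in files:
            self.data["checksums"][str(f.relative_to(outdir))] = _sha256(f)
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    seed = int(stage_seed(config.seed, "simulate").generate_state(1)[0])
    cohort = generate_cohort(config.cohort, seed)
    data_dir = outdir / "data"
    cohort.save(data_dir)
    return sorted(data_dir.iterdir())


def _load_trial_records(outdir: Path) -> dict[int, list]:
    trials = pd.read_csv(outdir / "data" / "trials.csv")
    return {
        int(s): frame_to_trials(g.sort_values("trial"))
        for s, g in trials.groupby("subject")
    }


def _stage_fit(config: RunConfig, outdir: Path) -> list[Path]:
    records = _load_trial_records(outdir)
    seeds = stage_seed(config.seed, "fit").spawn(len(config.fit_specs))
    fits: list[CohortFit] = []
    files = []
    for name, ss in zip(config.fit_specs, seeds):
        spec = ModelSpec.from_name(name)
        fit = fit_hierarchical_em(
            records,
            spec,
            max_iter=config.fit_max_iter,
            tol=config.fit_tol,
            seed=int(ss.generate_state(1)[0]),
            restarts=config.fit_restarts,
            warm_restarts=config.fit_warm_restarts,
            n_arms=config.cohort.task.n_arms,
        )
        if not fit.converged:
            log.warning("EM for %s hit max_iter without converging", name)
        fits.append(fit)
        p = outdir / f"fits_{name.replace('+', 'p').replace('-', 'm')}.json"
        p.write_text(fit.to_json())
        files.append(p)
    pd.concat([f.to_frame() for f in fits], ignore_index=True).to_csv(
        outdir / "fits.csv", index=False
    )
    compare_models(fits).to_csv(outdir / "model_comparison.csv", index=False)
    return files + [outdir / "fits.csv", outdir / "model_comparison.csv"]


def _stage_decode(config: RunConfig, outdir: Path) -> list[Path]:
    cohort = Cohort.load(outdir / "data")
    results: list[DecodeResult] = []
    for network in range(config.cohort.n_networks):
        results.extend(loso_decode(cohort.network_sessions(network), config.decoder))
    results_to_frame(results).to_csv(outdir / "decoding.csv", index=False)
    distances_to_frame(results).to_csv(outdir / "distances.csv", index=False)
    decoding_report(
        results, seed=int(stage_seed(config.seed, "decode").generate_state(1)[0])
    ).to_csv(outdir / "decoding_report.csv", index=False)
    return [outdir / "decoding.csv", outdir / "distances.csv", outdir / "decoding_report.csv"]


def _winning_spec(outdir: Path) -> str:
    comp = pd.read_csv(outdir / "model_comparison.csv")
    return str(comp.loc[comp["winner"], "spec"].iloc[0])


def _load_subject_fits(outdir: Path, spec_name: str) -> dict[int, object]:
    path = outdir / f"fits_{spec_name.replace('+', 'p').replace('-', 'm')}.json"
    payload = json.loads(path.read_text())
    spec = ModelSpec.from_name(payload["spec"])

    @dataclass
    class _Fit:
        params: AgentParams
        spec: ModelSpec

    return {
        int(s["subject"]): _Fit(
            AgentParams(s["alpha_pos"], s["alpha_neg"], s["beta"]), spec
        )
        for s in payload["subjects"]
    }


def _load_decode_results(outdir: Path) -> list[DecodeResult]:
    summary = pd.read_csv(outdir / "decoding.csv")
    dist = pd.read_csv(outdir / "distances.csv")
    grouped = {
        (int(s), int(n)): g.sort_values("trial")["distance"].to_numpy()
        for (s, n), g in dist.groupby(["subject", "network"])
    }
    return [
        DecodeResult(
            subject=int(r.subject),
            network=int(r.network),
            sensitivity=r.sensitivity,
            specificity=r.specificity,
            accuracy=r.accuracy,
            distances=grouped[(int(r.subject), int(r.network))],
        )
        for r in summary.itertuples(index=False)
    ]


def _build_table(config: RunConfig, outdir: Path) -> pd.DataFrame:
    winner = _winning_spec(outdir)
    fits = _load_subject_fits(outdir, winner)
    decode_results = _load_decode_results(outdir)
    covariates = pd.read_csv(outdir / "data" / "covariates.csv")
    records = _load_trial_records(outdir)
    return assemble_trial_table(fits, decode_results, covariates, records)


def _stage_couple(config: RunConfig, outdir: Path) -> list[Path]:
    table = _build_table(config, outdir)
    table.to_csv(outdir / "trial_table.csv", index=False)
    networks = sorted(table["network"].unique())
    m = len(networks)

    coupling_fits = [fit_coupling_lmem(table, n) for n in networks]
    cdf = coupling_results_to_frame(
        coupling_fits, flag_term="V", family_alpha=config.family_alpha
    )
    cdf.to_csv(outdir / "coupling.csv", index=False)
    files = [outdir / "trial_table.csv", outdir / "coupling.csv"]

    record = {
        "winning_spec": _winning_spec(outdir),
        "n_networks": m,
        "bonferroni_alpha": bonferroni_adjust([1.0], m, config.family_alpha)[0],
        "coupling_formula": coupling_fits[0].formula,
        "moderation_formulas": {},
    }
    for mod in config.moderators:
        fits = [fit_moderation_lmem(table, n, mod) for n in networks]
        mdf = coupling_results_to_frame(
            fits, flag_term=f"V:{mod}", family_alpha=config.family_alpha
        )
        p = outdir / f"moderation_{mod}.csv"
        mdf.to_csv(p, index=False)
        files.append(p)
        record["moderation_formulas"][mod] = fits[0].formula
    (outdir / "coupling_record.json").write_text(json.dumps(record, indent=1))
    return files + [outdir / "coupling_record.json"]


def _stage_mediate(config: RunConfig, outdir: Path) -> list[Path]:
    table = pd.read_csv(outdir / "trial_table.csv")
    winner = _winning_spec(outdir)
    fits = _load_subject_fits(outdir, winner)
    slopes = subject_coupling_slopes(table, config.cohort.striatum_network_index)
    subj = table.drop_duplicates("subject").set_index("subject")
    subjects = [s for s in slopes.index if s in subj.index]
    M = slopes.loc[subjects].to_numpy()
    Y = np.array([np.log(fits[s].params.beta) for s in subjects])
    C = subj.loc[subjects, ["log_ctq"]]
    seed = int(stage_seed(config.seed, "mediate").generate_state(1)[0])
    files = []
    for symptom in config.mediation_symptoms:
        X = subj.loc[subjects, symptom].to_numpy()
        result = mediation_bootstrap(
            X, M, Y, covariates=C, n_boot=config.mediation_n_boot, seed=seed
        )
        (outdir / f"mediation_{symptom}.json").write_text(result.to_json())
        (outdir / f"mediation_{symptom}.txt").write_text(
            f"X = {symptom}, M = striatum coupling slope, Y = log fitted beta\n"
            + result.text_report()
            + "\n"
        )
        files += [outdir / f"mediation_{symptom}.json", outdir / f"mediation_{symptom}.txt"]
    slopes.to_csv(outdir / "coupling_slopes.csv")
    return files + [outdir / "coupling_slopes.csv"]


def _fmt_table(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.4g}")


def _stage_report(config: RunConfig, outdir: Path) -> list[Path]:
    lines = ["# Pipeline report", ""]

    def section(title: str, path: Path, render):
        lines.append(f"## {title}")
        if path.exists():
            lines.append(render(path))
        else:
            lines.append(f"[missing: {path.name} not produced]")
        lines.append("")

    section(
        "Model comparison (summed AIC)",
        outdir / "model_comparison.csv",
        lambda p: _fmt_table(pd.read_csv(p)),
    )
    section(
        "Decoding accuracy by network",
        outdir / "decoding_report.csv",
        lambda p: _fmt_table(pd.read_csv(p)),
    )

    m = config.cohort.n_networks
    alpha = round_half_up(config.family_alpha / m, 4)

    def coupling_render(p: Path) -> str:
        return (
            f"Bonferroni-corrected alpha = {alpha} "
            f"({config.family_alpha}/{m} networks)\n" + _fmt_table(pd.read_csv(p))
        )

    section("Trial-level coupling", outdir / "coupling.csv", coupling_render)
    for mod in config.moderators:
        section(
            f"Moderation by {mod}",
            outdir / f"moderation_{mod}.csv",
            coupling_render,
        )
    for symptom in config.mediation_symptoms:
        section(
            f"Mediation ({symptom})",
            outdir / f"mediation_{symptom}.txt",
            lambda p: p.read_text(),
        )
    (outdir / "report.md").write_text("\n".join(lines))
    return [outdir / "report.md"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "decode": _stage_decode,
    "couple": _stage_couple,
    "mediate": _stage_mediate,
    "report": _stage_report,
}


def run_pipeline(config: RunConfig) -> Path:
    """Run the enabled stages in order; returns the run directory.

    A stage failure aborts the run with the stage named in the exception;
    outputs of earlier stages are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")
    manifest = _Manifest(outdir, config)
    for stage in STAGES:
        if not config.stages.get(stage, True):
            log.info("stage %s disabled; skipping", stage)
            continue
        t0 = time.perf_counter()
        try:
            files = _STAGE_FUNCS[stage](config, outdir)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
        wall = time.perf_counter() - t0
        manifest.record(stage, outdir, files, wall, n_files=len(files))
        log.info("stage %s done in %.1fs (%d files)", stage, wall, len(files))
    return outdir


def write_report(run_dir: str | Path) -> Path:
    """(Re)build the report for an existing run directory."""
    run_dir = Path(run_dir)
    config = RunConfig.load(run_dir / "config.yaml")
    _stage_report(config, run_dir)
    return run_dir / "report.md"
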