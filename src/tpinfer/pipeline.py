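"""Cohort orchestration: generate -> infer -> detect -> analyze.

`run_subject` carries one synthetic session through both observers and the
detection stage and assembles the per-question regressor table;
`run_cohort` does this for a group of simulated subjects with
stage-scoped seeded random streams; `run_pipeline` is the file-level
driver behind the command line: it validates a flat key-value config,
writes every stage's TSV outputs and records a manifest with checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .confidence import build_regressors, normalize_uncertainty
from .fb import PosteriorSummary, ThetaGrid, filtered_series, jump_posterior_matrix, windowed_jump_matrix
from .generative import AgentParams, GenerativeParams, Session, SubjectResponses, generate_session, simulate_agent
from .gibbs import GibbsConfig, chunk_length_stats, gibbs_sample
from .io import config_checksum, write_responses, write_session
from .jumps import DetectionConfig, classify_trials, discretize_jump_posterior, informedness

__all__ = [
    "PipelineConfig",
    "SubjectRun",
    "run_subject",
    "run_cohort",
    "run_study",
    "subject_table",
    "subject_responses",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated flat configuration of a full pipeline run."""

    seed: int
    n_subjects: int = 18
    generative: GenerativeParams = field(default_factory=GenerativeParams)
    p_jump: float = 1.0 / 75.0
    grid_k: int = 40
    window: int = 5
    gibbs_iterations: int = 200
    gibbs_warmup: int = 20
    detect_threshold: float = 0.25
    detect_window: int = 5
    n_surrogates: int = 10_000
    n_perm: int = 10_000
    agent: AgentParams = field(default_factory=AgentParams)

    _KEYS = {
        "seed": int,
        "n_subjects": int,
        "observer.p_jump": float,
        "observer.grid_k": int,
        "observer.window": int,
        "gibbs.iterations": int,
        "gibbs.warmup": int,
        "detect.threshold": float,
        "detect.window": int,
        "detect.n_surrogates": int,
        "analysis.n_perm": int,
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        from .io import params_from_config

        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        gen = {
            k[len("generative."):]: v
            for k, v in raw.items()
            if k.startswith("generative.")
        }
        rest = {k: v for k, v in raw.items() if not k.startswith("generative.")}
        unknown = set(rest) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        typed = {k: cls._KEYS[k](v) for k, v in rest.items()}
        return cls(
            seed=typed["seed"],
            n_subjects=typed.get("n_subjects", 18),
            generative=params_from_config(gen),
            p_jump=typed.get("observer.p_jump", 1.0 / 75.0),
            grid_k=typed.get("observer.grid_k", 40),
            window=typed.get("observer.window", 5),
            gibbs_iterations=typed.get("gibbs.iterations", 200),
            gibbs_warmup=typed.get("gibbs.warmup", 20),
            detect_threshold=typed.get("detect.threshold", 0.25),
            detect_window=typed.get("detect.window", 5),
            n_surrogates=typed.get("detect.n_surrogates", 10_000),
            n_perm=typed.get("analysis.n_perm", 10_000),
        )


@dataclass
class SubjectRun:
    """Everything computed for one simulated subject."""

    session: Session
    filtered: PosteriorSummary
    gamma: np.ndarray
    gamma_windowed: np.ndarray
    reports: list[tuple[int, int]]
    table: pd.DataFrame
    responses: Optional[SubjectResponses] = None

    @property
    def question_trials(self) -> pd.DataFrame:
        return self.table

    def classification(self, window: int = 5):
        return classify_trials(
            self.reports,
            self.session.jump_positions,
            self.session.n_stimuli,
            window,
        )


def run_subject(
    rng: np.random.Generator,
    gen_params: GenerativeParams = GenerativeParams(),
    p_jump: float = 1.0 / 75.0,
    grid: ThetaGrid = ThetaGrid(40),
    gibbs_config: Optional[GibbsConfig] = None,
    detection: DetectionConfig = DetectionConfig(),
    agent: Optional[AgentParams] = None,
    with_chunk_stats: bool = True,
) -> SubjectRun:
    """Run the full inference/detection stack on one generated session."""
    session = generate_session(gen_params, rng)
    filtered = filtered_series(session.stimuli, p_jump, grid)
    gamma = jump_posterior_matrix(session.stimuli, p_jump, grid)
    gamma_w = windowed_jump_matrix(gamma, detection.window)
    reports = discretize_jump_posterior(gamma, detection.threshold)

    chunk_mean = chunk_var = None
    if with_chunk_stats:
        cfg = gibbs_config or GibbsConfig(p_jump=p_jump)
        chunk_mean, chunk_var = [], []
        for t in session.question_positions:
            samples = gibbs_sample(session.stimuli[: int(t)], cfg, rng)
            m, v = chunk_length_stats(samples)
            chunk_mean.append(m)
            chunk_var.append(v)
        chunk_mean = np.asarray(chunk_mean)
        chunk_var = np.asarray(chunk_var)

    table = build_regressors(
        session, filtered, reports, chunk_mean, chunk_var
    )
    run = SubjectRun(
        session=session,
        filtered=filtered,
        gamma=gamma,
        gamma_windowed=gamma_w,
        reports=reports,
        table=table,
    )
    if agent is not None:
        agent_reports = (
            reports
            if agent.detection_threshold == detection.threshold
            else discretize_jump_posterior(gamma, agent.detection_threshold)
        )
        run.responses = simulate_agent(
            session,
            table["io_mean"].to_numpy(),
            table["io_confidence"].to_numpy(),
            agent_reports,
            agent,
            rng,
        )
    return run


def run_cohort(
    n_subjects: int,
    seed: int,
    gen_params: GenerativeParams = GenerativeParams(),
    p_jump: float = 1.0 / 75.0,
    grid: ThetaGrid = ThetaGrid(40),
    gibbs_config: Optional[GibbsConfig] = None,
    detection: DetectionConfig = DetectionConfig(),
    agent: Optional[AgentParams] = None,
    with_chunk_stats: bool = True,
) -> list[SubjectRun]:
    """Independent subject runs from per-subject seeded streams."""
    root = np.random.SeedSequence(seed)
    runs = []
    for child in root.spawn(n_subjects):
        runs.append(
            run_subject(
                np.random.default_rng(child),
                gen_params,
                p_jump,
                grid,
                gibbs_config,
                detection,
                agent,
                with_chunk_stats,
            )
        )
    if with_chunk_stats:
        normalize_uncertainty([r.table for r in runs])
    return runs


def run_study(
    n_subjects: int = 18,
    n_blocks: int = 4,
    seed: int = 0,
    gen_params: GenerativeParams = GenerativeParams(),
    p_jump: float = 1.0 / 75.0,
    grid: ThetaGrid = ThetaGrid(40),
    gibbs_config: Optional[GibbsConfig] = None,
    detection: DetectionConfig = DetectionConfig(),
    agent: Optional[AgentParams] = None,
    with_chunk_stats: bool = True,
) -> list[list[SubjectRun]]:
    """Simulate the full study design: n_subjects x n_blocks sessions.

    Returns one list of block runs per subject.  Jump-location uncertainty
    is normalized over matched question ordinals pooled across every block
    of every subject.
    """
    root = np.random.SeedSequence(seed)
    study: list[list[SubjectRun]] = []
    for subject_seq in root.spawn(n_subjects):
        rng = np.random.default_rng(subject_seq)
        study.append(
            [
                run_subject(
                    rng, gen_params, p_jump, grid, gibbs_config,
                    detection, agent, with_chunk_stats,
                )
                for _ in range(n_blocks)
            ]
        )
    if with_chunk_stats:
        normalize_uncertainty([r.table for runs in study for r in runs])
    return study


def subject_table(runs: list[SubjectRun]) -> pd.DataFrame:
    """All question trials of one subject, blocks concatenated."""
    parts = []
    for b, run in enumerate(runs):
        t = run.table.copy()
        t.insert(0, "block", b)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def subject_responses(runs: list[SubjectRun]) -> dict[str, np.ndarray]:
    """The subject's simulated answers, blocks concatenated."""
    return {
        "probability_estimates": np.concatenate(
            [r.responses.probability_estimates for r in runs]
        ),
        "confidence_ratings": np.concatenate(
            [r.responses.confidence_ratings for r in runs]
        ),
    }


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the staged pipeline, write TSVs and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw_cfg = {"seed": config.seed, "n_subjects": config.n_subjects}
    checksum = config_checksum(raw_cfg)
    manifest: dict = {
        "version": __version__,
        "config": raw_cfg,
        "config_checksum": checksum,
        "stages": {},
        "outputs": {},
    }
    stage = "run-all"
    try:
        t0 = time.perf_counter()
        stage = "generate+infer+detect"
        runs = run_cohort(
            config.n_subjects,
            config.seed,
            config.generative,
            config.p_jump,
            ThetaGrid(config.grid_k),
            GibbsConfig(
                config.gibbs_iterations, config.gibbs_warmup, config.p_jump
            ),
            DetectionConfig(config.detect_window, config.detect_threshold),
            agent=config.agent,
        )
        manifest["stages"][stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "write-outputs"
        inf_rows = []
        for i, run in enumerate(runs):
            write_session(run.session, out / f"session_{i:02d}.tsv", checksum)
            if run.responses is not None:
                write_responses(
                    run.responses,
                    out / f"responses_{i:02d}.tsv",
                    out / f"reports_{i:02d}.tsv",
                    checksum,
                )
            table = run.table.copy()
            table.insert(0, "subject", i)
            inf_rows.append(table)
        posterior = pd.concat(inf_rows, ignore_index=True)
        with open(out / "question_posteriors.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# stage: infer\n# config_checksum: {checksum}\n")
            posterior.to_csv(fh, sep="\t", index=False)

        scores = []
        for i, run in enumerate(runs):
            tc = run.classification(config.detect_window)
            scores.append(
                {
                    "subject": i,
                    "n_reports": len(run.reports),
                    "n_jumps": len(run.session.jump_positions),
                    "informedness": informedness(tc),
                }
            )
        score_df = pd.DataFrame(scores)
        with open(out / "detection_scores.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# stage: score\n# config_checksum: {checksum}\n")
            score_df.to_csv(fh, sep="\t", index=False)
        manifest["stages"][stage] = time.perf_counter() - t0

        for p in sorted(out.glob("*.tsv")):
            manifest["outputs"][p.name] = _file_checksum(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as err:
        raise RuntimeError(f"pipeline failed during stage '{stage}': {err}") from err
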