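"""File formats: session/response/posterior TSVs, configs, MAT import.

Everything the pipeline writes is tab-delimited UTF-8 text with '.' as the
decimal mark and 1-based stimulus positions.  Each file starts with
comment lines (prefixed '#') naming the producing stage and the config
checksum.  The MAT importer for the original behavioral dataset is kept
behind a single optional function so the core pipeline has no binary
format dependency.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .generative import GenerativeParams, Session, SubjectResponses

__all__ = [
    "write_session",
    "read_session",
    "write_responses",
    "read_responses",
    "read_config",
    "write_config",
    "config_checksum",
    "params_from_config",
    "import_matlab_dataset",
]

PathLike = Union[str, Path]


def _header(stage: str, checksum: Optional[str]) -> str:
    lines = [f"# stage: {stage}"]
    if checksum:
        lines.append(f"# config_checksum: {checksum}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: PathLike, stage: str, checksum: Optional[str]):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, checksum))
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: empty input file")
    return pd.read_csv(_io.StringIO(text), sep="\t", comment="#")


def write_session(
    session: Session, path: PathLike, checksum: Optional[str] = None
) -> None:
    """Write a session as TSV, one row per stimulus."""
    chunk = session.chunk_index()
    thetas = session.chunk_thetas[chunk]
    is_q = np.zeros(session.n_stimuli, dtype=np.int64)
    is_q[session.question_positions - 1] = 1
    df = pd.DataFrame(
        {
            "position": np.arange(1, session.n_stimuli + 1),
            "symbol": np.where(session.stimuli == 1, "A", "B"),
            "chunk_id": chunk + 1,
            "theta_A_given_B": thetas[:, 0],
            "theta_B_given_A": thetas[:, 1],
            "is_question": is_q,
        }
    )
    _write_tsv(df, path, "generate", checksum)


def read_session(path: PathLike) -> Session:
    """Read a session TSV back into a Session (inverse of write_session)."""
    df = _read_tsv(path)
    required = {
        "position", "symbol", "chunk_id",
        "theta_A_given_B", "theta_B_given_A", "is_question",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pos = df["position"].to_numpy()
    if not np.array_equal(pos, np.arange(1, len(df) + 1)):
        bad = int(np.flatnonzero(pos != np.arange(1, len(df) + 1))[0]) + 1
        raise ValueError(f"{path}: non-contiguous positions at data row {bad}")
    th = df[["theta_A_given_B", "theta_B_given_A"]].to_numpy()
    out_of_range = ~((th > 0) & (th < 1)).all(axis=1)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0]) + 1
        raise ValueError(f"{path}: transition probability outside (0,1) at data row {row}")
    bad_sym = ~df["symbol"].isin(["A", "B"])
    if bad_sym.any():
        row = int(np.flatnonzero(bad_sym)[0]) + 1
        raise ValueError(f"{path}: symbol must be A or B at data row {row}")
    stimuli = (df["symbol"] == "A").to_numpy().astype(np.int64)
    chunk = df["chunk_id"].to_numpy()
    jumps = np.flatnonzero(np.diff(chunk) != 0) + 2  # 1-based chunk starts
    starts = np.concatenate([[0], jumps - 1])
    chunk_thetas = th[starts]
    questions = pos[df["is_question"].to_numpy() == 1]
    return Session(
        stimuli=stimuli,
        jump_positions=jumps.astype(np.int64),
        chunk_thetas=chunk_thetas,
        question_positions=questions.astype(np.int64),
    )


def write_responses(
    responses: SubjectResponses,
    questions_path: PathLike,
    reports_path: PathLike,
    checksum: Optional[str] = None,
) -> None:
    qdf = pd.DataFrame(
        {
            "position": responses.question_positions,
            "probability_estimate": responses.probability_estimates,
            "confidence_rating": responses.confidence_ratings,
        }
    )
    rdf = pd.DataFrame(
        {
            "report_time": responses.report_times,
            "reported_position": responses.reported_positions,
        }
    )
    _write_tsv(qdf, questions_path, "simulate-agents", checksum)
    _write_tsv(rdf, reports_path, "simulate-agents", checksum)


def read_responses(
    questions_path: PathLike, reports_path: PathLike
) -> SubjectResponses:
    qdf = _read_tsv(questions_path)
    rdf = _read_tsv(reports_path)
    return SubjectResponses(
        question_positions=qdf["position"].to_numpy(dtype=np.int64),
        probability_estimates=qdf["probability_estimate"].to_numpy(dtype=float),
        confidence_ratings=qdf["confidence_rating"].to_numpy(dtype=float),
        report_times=rdf["report_time"].to_numpy(dtype=np.int64),
        reported_positions=rdf["reported_position"].to_numpy(dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# flat key-value configs


def read_config(path: PathLike) -> dict[str, str]:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def write_config(config: dict, path: PathLike) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in config.items()), encoding="utf-8"
    )


def config_checksum(config: dict) -> str:
    blob = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


_GEN_KEYS = {
    "session_length": int,
    "mean_chunk_length": float,
    "max_chunk_length": int,
    "theta_low": float,
    "theta_high": float,
    "min_odds_ratio_change": float,
    "question_period": int,
    "seed": int,
}


def params_from_config(config: dict[str, str]) -> GenerativeParams:
    """Build GenerativeParams from flat config keys; unknown keys rejected."""
    kwargs = {}
    for key, value in config.items():
        if key == "question_jitter_magnitudes":
            kwargs[key] = tuple(int(v) for v in str(value).split(","))
        elif key in _GEN_KEYS:
            kwargs[key] = _GEN_KEYS[key](value)
        else:
            raise ValueError(f"unknown generative config key: {key}")
    return GenerativeParams(**kwargs)


# ---------------------------------------------------------------------------
# MAT import of the original behavioral dataset


def import_matlab_dataset(path: PathLike) -> list[dict]:
    """Import the deposited behavioral dataset (MAT file).

    Expects one record per subject x block with fields for the stimulus
    sequence, jump positions, generative transition probabilities, question
    positions, probability estimates, confidence ratings and jump reports;
    returns a list of dicts with a Session, a SubjectResponses and a side
    table of any unmapped fields.  Fails with the encountered field names
    if the layout is not recognized.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    from scipy.io import loadmat

    try:
        mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    except Exception as err:  # truncated / not a MAT file
        raise ValueError(f"{path}: cannot read MAT file ({err})") from err
    records = None
    for key, value in mat.items():
        if key.startswith("__"):
            continue
        records = np.atleast_1d(value)
        break
    if records is None:
        raise ValueError(f"{path}: no data variables found")

    out = []
    for rec in records:
        fields = {f: getattr(rec, f) for f in getattr(rec, "_fieldnames", [])}
        needed = {
            "stimuli", "jump_positions", "chunk_thetas", "question_positions",
            "probability_estimates", "confidence_ratings",
            "report_times", "reported_positions",
        }
        if not needed <= set(fields):
            raise ValueError(
                f"{path}: unrecognized record layout; encountered fields "
                f"{sorted(fields) or sorted(vars(rec))}"
            )
        session = Session(
            stimuli=np.asarray(fields["stimuli"], dtype=np.int64).ravel(),
            jump_positions=np.asarray(
                fields["jump_positions"], dtype=np.int64
            ).ravel(),
            chunk_thetas=np.atleast_2d(
                np.asarray(fields["chunk_thetas"], dtype=float)
            ),
            question_positions=np.asarray(
                fields["question_positions"], dtype=np.int64
            ).ravel(),
        )
        responses = SubjectResponses(
            question_positions=session.question_positions.copy(),
            probability_estimates=np.asarray(
                fields["probability_estimates"], dtype=float
            ).ravel(),
            confidence_ratings=np.asarray(
                fields["confidence_ratings"], dtype=float
            ).ravel(),
            report_times=np.asarray(fields["report_times"], dtype=np.int64).ravel(),
            reported_positions=np.asarray(
                fields["reported_positions"], dtype=np.int64
            ).ravel(),
        )
        side = {k: v for k, v in fields.items() if k not in needed}
        out.append(
            {"session": session, "responses": responses, "extra": side}
        )
    return out
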