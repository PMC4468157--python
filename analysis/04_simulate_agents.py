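"""Simulate noisy-readout subjects from the observer outputs.

Each agent reports the observer's posterior-mean probability plus Gaussian
noise (and occasional lapses) at every question, a noisy affine readout of
the observer's log-precision as its confidence rating, and the observer's
thresholded jump reports.  These agents close the loop: the downstream
analyses should recover the readout structure from their responses alone.
Writes per-block response tables under results/agents/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tpinfer.generative import AgentParams, simulate_agent
from tpinfer.io import read_session, write_responses

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--sessions", type=Path, default=ROOT / "results" / "sessions")
    ap.add_argument("--observer", type=Path, default=ROOT / "results" / "observer")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "agents")
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    agent = AgentParams()
    rng = np.random.default_rng(args.seed)
    n = 0
    for path in sorted(args.sessions.glob("subject*_block*.tsv")):
        session = read_session(path)
        table = pd.read_csv(
            args.observer / f"{path.stem}_questions.tsv", sep="\t"
        )
        rep_df = pd.read_csv(
            args.observer / f"{path.stem}_reports.tsv", sep="\t"
        )
        responses = simulate_agent(
            session,
            table["io_mean"].to_numpy(),
            table["io_confidence"].to_numpy(),
            list(zip(rep_df["report_time"], rep_df["reported_position"])),
            agent,
            rng,
        )
        write_responses(
            responses,
            args.out / f"{path.stem}_responses.tsv",
            args.out / f"{path.stem}_reports.tsv",
        )
        n += 1
    print(
        f"simulated {n} agent blocks "
        f"(estimate noise sd {agent.estimate_noise_sd}, confidence readout "
        f"{agent.confidence_offset} + {agent.confidence_gain} x log-precision "
        f"+ N(0, {agent.confidence_noise_sd}), lapse rate {agent.lapse_rate})"
    )


if __name__ == "__main__":
    main()
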