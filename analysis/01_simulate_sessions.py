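"""Simulate the study's stimulus sessions.

Generates the synthetic cohort — by default 18 subjects x 4 blocks of 380
binary stimuli, with geometric chunks (mean 75, capped at 300), per-chunk
transition probabilities uniform on [0.1, 0.9] under the odds-ratio-change
constraint, and questions every 15 +/- {1,2,3} stimuli — and writes one
session TSV per block under results/sessions/.
"""

import argparse
from pathlib import Path

import numpy as np

from tpinfer.generative import GenerativeParams, generate_session
from tpinfer.io import write_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20260920)
    ap.add_argument("--n-subjects", type=int, default=18)
    ap.add_argument("--n-blocks", type=int, default=4)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "sessions")
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(args.seed)
    n_jumps = []
    for s, subject_seq in enumerate(root.spawn(args.n_subjects)):
        rng = np.random.default_rng(subject_seq)
        for b in range(args.n_blocks):
            session = generate_session(GenerativeParams(), rng)
            write_session(
                session, args.out / f"subject{s:02d}_block{b}.tsv"
            )
            n_jumps.append(len(session.jump_positions))
    print(
        f"wrote {args.n_subjects * args.n_blocks} sessions to {args.out}\n"
        f"jumps per session: mean {np.mean(n_jumps):.2f}, "
        f"range {min(n_jumps)}-{max(n_jumps)} "
        f"(expected ~{380 / 75 - 1:.1f} for geometric chunks of mean 75)"
    )


if __name__ == "__main__":
    main()
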