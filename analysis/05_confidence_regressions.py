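"""Confidence analyses: sign battery, recovery, accuracy correlations.

Runs the full regression program on the observer's own confidence and on
the simulated agents' responses:

  (1) the sign battery of the observer's log-precision confidence against
      model revision (-), log sample count (+), relevant transition
      entropy (-), irrelevant transition entropy (null) and jump-location
      uncertainty (-), plus the U-shape of confidence in the probability
      estimate;
  (2) recovery of the agents' readout: estimates track the observer's
      posterior mean, ratings its log-precision, and a residual
      confidence effect survives the four-factor heuristic regression;
  (3) accuracy correlations between and within subjects with their
      shuffle nulls, and the confidence-predicts-error statistic against
      its three reassignment controls.  Note that the default agents use
      independent readout noise on their two answers and one shared noise
      level across subjects, so the accuracy couplings are expected to be
      null here — they turn positive only for agents whose two answers
      share a per-subject precision (exercised in the test suite).

Writes group statistics to results/confidence/group_stats.tsv.
"""

import argparse
import re
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from tpinfer.confidence import (
    accuracy_correlations,
    affine_align,
    confidence_factor_analysis,
    error_confidence_controls,
    group_ttest,
    normalize_uncertainty,
    shuffle_nulls,
    subject_regression,
    ushape_fit,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=4)
    ap.add_argument("--observer", type=Path, default=ROOT / "results" / "observer")
    ap.add_argument("--agents", type=Path, default=ROOT / "results" / "agents")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "confidence")
    ap.add_argument("--n-perm", type=int, default=2000)
    ap.add_argument("--n-sim", type=int, default=500)
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    block_tables = {}
    for path in sorted(args.observer.glob("subject*_questions.tsv")):
        block_tables[path.stem.replace("_questions", "")] = pd.read_csv(
            path, sep="\t"
        )
    normalize_uncertainty(list(block_tables.values()))

    subjects = defaultdict(list)
    for stem in block_tables:
        subjects[int(re.match(r"subject(\d+)_", stem).group(1))].append(stem)

    tables, est, conf = [], [], []
    for s in sorted(subjects):
        tables.append(
            pd.concat(
                [block_tables[st] for st in sorted(subjects[s])],
                ignore_index=True,
            )
        )
        e, c = [], []
        for st in sorted(subjects[s]):
            resp = pd.read_csv(
                args.agents / f"{st}_responses.tsv", sep="\t", comment="#"
            )
            e.append(resp["probability_estimate"].to_numpy())
            c.append(resp["confidence_rating"].to_numpy())
        est.append(np.concatenate(e))
        conf.append(np.concatenate(c))

    rows = []

    def log(name, stat, note=""):
        rows.append({"analysis": name, "t": stat.t, "p": stat.p, "note": note})
        print(f"  {name:36s} t = {stat.t:7.2f}  p = {stat.p:.2e}  {note}")

    print("Sign battery on the observer's own confidence:")
    io_conf = [t["io_confidence"].to_numpy() for t in tables]
    battery = confidence_factor_analysis(io_conf, tables)
    log("io: model revision", battery["model_revision"], "expect -")
    log("io: log sample count", battery["log_sample_count"], "expect +")
    log("io: relevant entropy", battery["entropy_relevant"], "expect -")
    log("io: irrelevant entropy", battery["entropy_irrelevant"], "expect null")
    log(
        "io: jump-location uncertainty",
        battery["jump_location_uncertainty"],
        "expect -",
    )
    log(
        "io: U-shape in estimate",
        group_ttest(
            np.array(
                [
                    ushape_fit(t["io_confidence"].to_numpy(), t["io_mean"].to_numpy())
                    for t in tables
                ]
            )
        ),
        "expect +",
    )

    print("Agent readout recovery:")
    log(
        "agent estimates ~ io mean",
        group_ttest(
            np.array(
                [
                    subject_regression(e, t["io_mean"].to_numpy()[:, None], ["m"])[0]
                    for e, t in zip(est, tables)
                ]
            )
        ),
        "expect +",
    )
    log(
        "agent ratings ~ io confidence",
        group_ttest(
            np.array(
                [
                    subject_regression(
                        c, t["io_confidence"].to_numpy()[:, None], ["c"]
                    )[0]
                    for c, t in zip(conf, tables)
                ]
            )
        ),
        "expect +",
    )
    agent_battery = confidence_factor_analysis(conf, tables)
    log(
        "agent residual ~ io confidence",
        agent_battery["residual_io"],
        "full-posterior readout",
    )

    print("Accuracy correlations and controls:")
    io_est = [t["io_mean"].to_numpy() for t in tables]
    acc = accuracy_correlations(est, conf, io_est, io_conf)
    rows.append(
        {
            "analysis": "between-subject accuracy correlation",
            "t": np.nan,
            "p": acc.between_p,
            "note": f"r = {acc.between_r:.3f}",
        }
    )
    print(
        f"  between-subject accuracies: r = {acc.between_r:.3f} "
        f"(p = {acc.between_p:.2e})  [default agents share one noise level "
        f"across subjects: no coupling expected]"
    )
    log(
        "within-subject error correlation",
        acc.within_group,
        "independent readout noise: expect null",
    )

    aligned = [affine_align(c, oc) for c, oc in zip(conf, io_conf)]
    nulls = shuffle_nulls(
        est, aligned, io_est, io_conf, n_perm=args.n_perm, rng=rng
    )
    print(
        f"  shuffle nulls: p = {nulls['p_vs_shuffle1']:.4f} (order only), "
        f"p = {nulls['p_vs_shuffle2']:.4f} (order + mapping)"
    )
    rows.append(
        {
            "analysis": "within vs shuffle (keep pairs)",
            "t": nulls["observed_t"],
            "p": nulls["p_vs_shuffle1"],
            "note": f"{args.n_perm} permutations",
        }
    )

    gen = [t["generative_prob_next_A"].to_numpy() for t in tables]
    controls = error_confidence_controls(
        est, conf, gen, n_sim=args.n_sim, rng=rng
    )
    ps = controls["p_values"]
    print(
        f"  confidence predicts error: t = {controls['observed_t']:.2f}; "
        f"reassignment controls p = "
        f"{ps['estimates']:.3f} / {ps['confidence']:.3f} / {ps['generative']:.3f}"
    )
    for name, p in ps.items():
        rows.append(
            {
                "analysis": f"error control: shuffle {name}",
                "t": controls["observed_t"],
                "p": p,
                "note": f"{args.n_sim} reassignments",
            }
        )

    pd.DataFrame(rows).to_csv(args.out / "group_stats.tsv", sep="\t", index=False)
    print(f"wrote {args.out / 'group_stats.tsv'}")


if __name__ == "__main__":
    main()
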