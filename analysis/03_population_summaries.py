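"""Population outputs: fraction-localized curves, medians, classes, U-tests.

For each condition this writes the instantaneous fraction-localized curve and
a JSON summary (median total nuclear time, median time to first localization
over responders, class tallies), then compares total nuclear time between
adjacent stress strengths with the one-sided Mann-Whitney U test.

Run:  python analysis/03_population_summaries.py
"""

import argparse
import json
from pathlib import Path

import numpy as np

import nucloc as nl
from nucloc.pipeline import write_summary
from nucloc.tables import read_metrics, read_state_tracks


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--conditions", type=Path, default=Path("results/conditions"))
    parser.add_argument("--out", type=Path, default=Path("results/population"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    summaries = {}
    totals = {}
    for states_path in sorted(args.conditions.glob("*_states.tsv")):
        label = states_path.stem.removesuffix("_states")
        tracks, _ = read_state_tracks(states_path)
        metrics = read_metrics(states_path.with_name(f"{label}_metrics.tsv"))
        summary = nl.summarize_condition(metrics, tracks, label=label)
        write_summary(args.out / f"{label}_summary.json", summary)
        times, frac = nl.fraction_localized(tracks)
        np.savetxt(
            args.out / f"{label}_fraction_localized.tsv",
            np.column_stack([times, frac]),
            delimiter="\t",
            header="time_s\tfraction_localized",
            comments="# ",
        )
        summaries[label] = summary
        totals[label] = [m.total_nuclear_time for m in metrics]
        first = summary.median_first_localization_time
        print(
            f"{label:>12}: median total nuclear time "
            f"{summary.median_total_nuclear_time / 60:5.1f} min, "
            f"median first localization "
            f"{'censored' if first is None else f'{first / 60:.1f} min'} "
            f"({summary.n_censored} censored), classes {summary.class_counts}"
        )

    pairs = [("weak", "intermediate"), ("intermediate", "strong")]
    tests = {}
    for lo, hi in pairs:
        if lo in totals and hi in totals:
            res = nl.mann_whitney(totals[lo], totals[hi], sided="greater")
            tests[f"{hi}_vs_{lo}"] = {
                "U": res.U, "n1": res.n1, "n2": res.n2,
                "p_value": res.p_value, "method": res.method,
            }
            print(
                f"total nuclear time, {hi} > {lo}: "
                f"U = {res.U:.0f}, p = {res.p_value:.2e} ({res.method})"
            )
    (args.out / "utests.json").write_text(json.dumps(tests, indent=2) + "\n")


if __name__ == "__main__":
    main()
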