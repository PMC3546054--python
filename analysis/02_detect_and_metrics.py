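"""Detect nuclear-localization states and per-cell metrics for each condition.

Applies the standard detection settings (5-frame moving average, threshold
0.28, 5-frame run cleanup) to the trajectory tables written by
01_simulate_conditions.py and writes state tracks and per-cell metrics next
to them.

Run:  python analysis/02_detect_and_metrics.py
"""

import argparse
from pathlib import Path

import nucloc as nl
from nucloc.tables import (
    read_trajectories,
    write_metrics,
    write_state_tracks,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--conditions", type=Path, default=Path("results/conditions"))
    args = parser.parse_args()
    params = nl.AnalysisParams()

    for table in sorted(args.conditions.glob("*.tsv")):
        if table.stem.endswith(("_states", "_metrics")):
            continue
        trajs, meta = read_trajectories(table)
        tracks = [nl.detect_states(t, params) for t in trajs]
        metrics = [nl.cell_metrics(t, params) for t in tracks]
        write_state_tracks(table.with_name(f"{table.stem}_states.tsv"), tracks, meta)
        write_metrics(table.with_name(f"{table.stem}_metrics.tsv"), metrics)
        n_resp = sum(m.responded for m in metrics)
        print(
            f"{table.stem:>12}: {len(metrics)} cells, {n_resp} responders "
            f"({100 * n_resp / len(metrics):.0f}%)"
        )


if __name__ == "__main__":
    main()
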