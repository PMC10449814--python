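#!/usr/bin/env python
"""Temporal-transfer ladder: how accuracy degrades with appearance drift.

Reloads the selected model of the desk run and evaluates it on
phenology-perturbed versions of the test scene at increasing drift strength.
The mask never changes — only the appearance does — so the drop in mean F1
isolates the effect of class-conditional colour/texture change, emulating
re-surveying the same plots in a different season.
"""

from pathlib import Path

import pandas as pd

from savseg.pipeline import load_run, temporal_transfer_eval

RESULTS = Path(__file__).resolve().parents[1] / "results"
RUN_DIR = Path(__file__).resolve().parents[1] / "scratch" / "desk_run"


def main():
    run = load_run(RUN_DIR)
    table = temporal_transfer_eval(run, [0.0, 0.25, 0.5, 0.75, 1.0])
    df = pd.DataFrame(table)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "temporal_transfer.csv", index=False)
    print(df.to_string(index=False))
    drop = table[0]["mean_f1"] - table[-1]["mean_f1"]
    print(f"\nMean F1 drops by {drop:.3f} from strength 0 to 1: a model "
          "trained on one season's appearance does not transfer once the "
          "vegetation's appearance drifts.")


if __name__ == "__main__":
    main()
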