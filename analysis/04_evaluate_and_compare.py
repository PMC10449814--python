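#!/usr/bin/env python
"""Per-class accuracy, architecture comparison, and landscape regressions.

Reads the trained run of 03_train_models.py and reports: per-class F1 for
each architecture, a paired t-test on the per-class F1 vectors (does the
architecture matter?), and OLS regressions of class F1 on the landscape
metrics of the training masks (patch area, class area, compactness).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from savseg.evaluation import paired_f1_test
from savseg.landscape import class_landscape_metrics, f1_metric_regression
from savseg.pipeline import load_run

RESULTS = Path(__file__).resolve().parents[1] / "results"
RUN_DIR = Path(__file__).resolve().parents[1] / "scratch" / "desk_run"


def main():
    cells = json.loads((RUN_DIR / "summary.json").read_text())
    run = load_run(RUN_DIR)
    class_table = run["scenes"]["train_0"].class_table

    per_class = pd.DataFrame({"class": [name for _, name in class_table]})
    for key, cell in cells.items():
        per_class[cell["architecture"]] = np.round(cell["per_class_f1"], 4)
    RESULTS.mkdir(exist_ok=True)
    per_class.to_csv(RESULTS / "per_class_f1.csv", index=False)
    print("Per-class F1 on the held-out test scene:")
    print(per_class.to_string(index=False))

    archs = [cell["architecture"] for cell in cells.values()]
    if len(archs) >= 2:
        a, b = (np.array(cells[k]["per_class_f1"]) for k in list(cells)[:2])
        try:
            t, p, df = paired_f1_test(a, b)
            print(f"\nPaired t-test {archs[0]} vs {archs[1]}: "
                  f"t = {t:.3f}, p = {p:.3f}, df = {df}")
        except ValueError as exc:
            print(f"\nPaired t-test degenerate: {exc}")

    # F1 vs landscape metrics of the training masks
    train_masks = np.concatenate(
        [run["scenes"][sid].mask for sid in run["split"].scenes("train")], axis=1)
    metrics = class_landscape_metrics(train_masks, class_table,
                                      gsd_cm=run["scenes"]["train_0"].gsd_cm,
                                      background_id=class_table[0][0])
    veg = [m for m in metrics if not m.is_background and m.n_patches > 0]
    rows = []
    for key, cell in cells.items():
        f1 = {i: v for i, v in enumerate(cell["per_class_f1"])}
        for metric_name in ("mean_patch_area_ha", "total_class_area_ha",
                            "mean_compactness"):
            xs = [getattr(m, metric_name) for m in veg]
            ys = [f1[m.class_id] for m in veg]
            if len(xs) < 3:
                rows.append({"model": cell["architecture"], "metric": metric_name,
                             "slope": np.nan, "p_value": np.nan, "df": len(xs) - 2,
                             "note": "needs >= 3 vegetation classes"})
                continue
            try:
                slope, _, p, df = f1_metric_regression(xs, ys)
                rows.append({"model": cell["architecture"], "metric": metric_name,
                             "slope": round(slope, 4), "p_value": round(p, 4),
                             "df": df, "note": ""})
            except ValueError as exc:
                rows.append({"model": cell["architecture"], "metric": metric_name,
                             "slope": np.nan, "p_value": np.nan,
                             "df": len(xs) - 2, "note": str(exc)})
    reg = pd.DataFrame(rows)
    reg.to_csv(RESULTS / "f1_landscape_regressions.csv", index=False)
    print("\nF1 ~ landscape-metric regressions (background excluded):")
    print(reg.to_string(index=False))
    print("\nWith only two vegetation classes in the desk preset the "
          "regression is reported but not meaningful; run the savanna "
          "preset for a 16-class version.")


if __name__ == "__main__":
    main()
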