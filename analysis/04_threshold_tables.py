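"""Predicted mortality at the 0.1 / 0.25 / 1.0 ug/kg/min cut-offs.

Two routes to the same table:

1. *fitted* — evaluate the logistic fitted to the simulated cohort at each
   reported-dose threshold under each convention (with delta-method CIs);
2. *anchored* — solve the two-parameter logistic through the published
   base-molecule anchor cells and propagate it by prediction equivariance
   p_f(d) = p_base(d / c_f).

Their agreement shows that the headline distortion — e.g. 83% vs 54%
predicted mortality at a reported 1.0 ug/kg/min peak dose depending on
whether base or tartrate is meant — follows from the reporting convention
alone.  Writes results/threshold_tables.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from nedose.model import fit_dose_response, fit_from_anchors, stack_formulations, threshold_table
from nedose.simulate import DIAGNOSIS_DOSE_ANCHORS, PEAK_DOSE_ANCHORS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "threshold_tables.csv")
    args = ap.parse_args()

    cohort = pd.read_csv(args.cohort)
    anchors = {"diagnosis": DIAGNOSIS_DOSE_ANCHORS, "peak": PEAK_DOSE_ANCHORS}
    frames = []
    for label, col in (("diagnosis", "diagnosis_dose"), ("peak", "peak_dose_24h")):
        fitted = threshold_table(fit_dose_response(stack_formulations(cohort, col)))
        fitted["route"] = "fitted"
        anchored = threshold_table(fit_from_anchors(anchors[label]))
        anchored["route"] = "anchored"
        both = pd.concat([fitted, anchored], ignore_index=True)
        both["dose_variable"] = label
        frames.append(both)

        print(f"\n{label} dose — predicted mortality (integer %):")
        pivot = both.pivot_table(
            index="threshold", columns=["formulation", "route"], values="percent"
        ).astype(int)
        print(pivot[["base", "hydrochloride", "bitartrate", "tartrate"]])

    out = pd.concat(frames, ignore_index=True)
    out.to_csv(args.out, index=False)

    peak = frames[1]
    a = peak[(peak.route == "anchored")].set_index(["formulation", "threshold"])["percent"]
    print(
        "\nbase-vs-tartrate divergence (anchored peak curve): "
        f"{a[('base', 0.1)] - a[('tartrate', 0.1)]} points at 0.1, "
        f"{a[('base', 1.0)] - a[('tartrate', 1.0)]} points at 1.0 ug/kg/min"
    )
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
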