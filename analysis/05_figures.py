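"""Dose-response curves and dose histograms.

Draws the sigmoid mortality curves per reporting convention with the three
threshold guide lines (0.1, 0.25, 1.0 ug/kg/min) for the fitted diagnosis-
and peak-dose models, and writes binned dose-frequency tables per convention.
Figures go to results/figures/, histogram tables to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from nedose.model import fit_dose_response, stack_formulations
from nedose.pipeline import plot_dose_response, summarize_distributions

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    cohort = pd.read_csv(args.cohort)
    figdir = args.out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    hists = []
    for label, col in (("diagnosis", "diagnosis_dose"), ("peak", "peak_dose_24h")):
        fit = fit_dose_response(stack_formulations(cohort, col))
        path = figdir / f"dose_response_{label}.png"
        plot_dose_response(fit, path)
        print(f"wrote {path}")
        hists.append(summarize_distributions(cohort, col).assign(dose_variable=label))

    hist = pd.concat(hists, ignore_index=True)
    hist.to_csv(args.out / "dose_histograms.csv", index=False)
    print(f"wrote {args.out / 'dose_histograms.csv'} ({len(hist)} bins)")


if __name__ == "__main__":
    main()
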