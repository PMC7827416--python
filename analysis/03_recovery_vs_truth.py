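#!/usr/bin/env python
"""Score the pipeline's calls against the planted truth.

Joins the classification, non-additivity, bias-transition and silencing
outputs in results/run/ with the generator's truth table and reports
per-class recall/precision, the conserved false-positive rate and exact
silencing/activation recovery. Writes confusion tables under
results/recovery/.
"""

from pathlib import Path

import pandas as pd

from alloexpr.io import write_table
from alloexpr.simulate import evaluate_recovery

SIM = Path("results/sim")
RUN = Path("results/run")
OUT = Path("results/recovery")

PATTERN_CLASSES = ["CONSERVED", "ADDITIVE", "ELD_A", "ELD_C", "TRANS_UP", "TRANS_DOWN"]


def main() -> None:
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t").set_index("pair_id")
    individuals = sorted(
        p.name.removeprefix("eld_").removesuffix(".tsv")
        for p in RUN.glob("eld_AACC*.tsv")
        if "summary" not in p.name
    )
    rows = []
    for ind in individuals:
        eld = pd.read_csv(RUN / f"eld_{ind}.tsv", sep="\t").set_index("pair_id")
        sub = truth[truth["planted_class"].isin(PATTERN_CLASSES)]
        rec = evaluate_recovery(sub["planted_class"], eld.loc[sub.index, "pattern"])
        rec.insert(0, "individual", ind)
        rows.append(rec)
        nonadd = pd.read_csv(RUN / f"nonadditive_{ind}.tsv", sep="\t").set_index("unit_id")
        na_recall = nonadd.loc[truth.index[truth["nonadditive"]], "nonadditive"].mean()
        bias = pd.read_csv(RUN / f"bias_{ind}.tsv", sep="\t").set_index("pair_id")
        trans_acc = (bias.loc[truth.index, "transition"] == truth["transition"]).mean()
        conserved = truth.index[truth["planted_class"] == "CONSERVED"]
        fp = (eld.loc[conserved, "pattern"] != "CONSERVED").mean()
        print(
            f"{ind}: nonadditive recall {na_recall:.3f}, "
            f"transition accuracy {trans_acc:.3f}, conserved FP {fp:.3f}"
        )
    confusion = pd.concat(rows, ignore_index=True)
    write_table(confusion, OUT / "pattern_recovery.tsv")
    mean_recall = (
        confusion[confusion["class"].isin(PATTERN_CLASSES)]
        .groupby("class")[["recall", "precision"]]
        .mean()
        .round(3)
    )
    print("\nmean recall/precision over individuals:")
    print(mean_recall.to_string())
    print(f"\nwritten to {OUT}/")


if __name__ == "__main__":
    main()
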