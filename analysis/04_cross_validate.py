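"""Leave-one-quarter-out cross-validation of the three estimators.

Holds each quarter out in turn, refits the log-quadratic model on the
other 24, and predicts the holdout's cumulative cause-specific mortality
with k = 0, with k calibrated to the observed cause-specific NMR, and
with the constant-daily-rate baseline.  Writes the averaged error table
(results/cv_summary.csv, 5 decimal places) and per-holdout detail.
"""

from pathlib import Path

from neoquad import loqo_cv, read_life_tables_csv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tables = read_life_tables_csv(OUT / "life_tables.csv")
    res = loqo_cv(tables)
    table1 = res.to_table1_frame()
    table1.to_csv(OUT / "cv_summary.csv", index=False)
    res.details.to_csv(OUT / "cv_details.csv", index=False)
    print(table1.to_string(index=False))
    print(
        "\nNote the structural zeros at 0h-4weeks: best-k calibration and the\n"
        "constant-daily-rate baseline both reproduce the observed 28-day\n"
        "cause-specific NMR exactly, so their cross-validation error there is 0."
    )


if __name__ == "__main__":
    main()
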