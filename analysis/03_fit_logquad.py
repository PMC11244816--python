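"""Fit the adapted log-quadratic model on all 25 quarters, per cause.

One JSON per modelled cause (preterm, asphyxia, sepsis, pneumonia,
congenital): quadratic coefficients per cumulative age, the deviation
vector v (normalized to 1 at 28 days), and training metadata.
"""

from pathlib import Path

from neoquad import fit_logquad, read_life_tables_csv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tables = read_life_tables_csv(OUT / "life_tables.csv")
    for cause in (c for c in tables[0].causes if c != "other"):
        fit = fit_logquad(tables, cause)
        fit.to_json(OUT / f"fit_{cause}.json")
        b = ", ".join(f"{x:+.2f}" for x in fit.b)
        v = ", ".join(f"{x:+.2f}" for x in fit.v)
        print(f"{cause:>10}: b = [{b}]  v = [{v}]")
    print(f"fits written to {OUT}/fit_<cause>.json")


if __name__ == "__main__":
    main()
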