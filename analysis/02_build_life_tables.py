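"""Filter the cohort and aggregate quarterly life tables.

Applies the analyzability filters (known death time, verbal autopsy
done), assigns each death to an age band and calendar quarter, and
writes the quarterly cumulative cause-specific mortality table to
results/life_tables.csv with the exclusion tally alongside.
"""

import json
from pathlib import Path

from neoquad import (
    build_quarter_tables,
    filter_analyzable,
    read_births_csv,
    read_cohort_csv,
    write_life_tables_csv,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_cohort_csv(OUT / "cohort.csv")
    retained, filter_tally = filter_analyzable(records)
    tables, build_tally = build_quarter_tables(retained, read_births_csv(OUT / "births.csv"))
    write_life_tables_csv(tables, OUT / "life_tables.csv")
    tally = {**filter_tally, **build_tally}
    with open(OUT / "exclusions.json", "w") as fh:
        json.dump(tally, fh, indent=1, sort_keys=True)
        fh.write("\n")
    print(
        f"retained {len(retained)}/{len(records)} deaths "
        f"({100 * len(retained) / len(records):.0f}%); exclusions: {tally}"
    )
    print(f"built {len(tables)} quarterly life tables; "
          f"NMR range {min(t.nmr for t in tables) * 1000:.1f}"
          f"-{max(t.nmr for t in tables) * 1000:.1f} per 1000")


if __name__ == "__main__":
    main()
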