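"""Observed vs predicted cumulative mortality, per cause and holdout quarter.

The graphical analogue of the cross-validation: for the first six
holdout quarters, the observed cumulative cause-specific mortality at
the four age bounds against the three predictors.  One PNG per cause
under results/figures/.
"""

import subprocess
import sys
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fig_dir = OUT / "figures"
    subprocess.run(
        [
            sys.executable, "-m", "neoquad.cli", "plot",
            "--tables", str(OUT / "life_tables.csv"),
            "--out-dir", str(fig_dir),
        ],
        check=True,
    )
    print(f"figures written under {fig_dir}")


if __name__ == "__main__":
    main()
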