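"""Fermentation kinetics of the deletion strains.

Simulates noise-free fermentation courses for the parent and two reduced
strains from their published specific rates, recomputes mu, the three
molar phenazine production rates, the mass-basis total rate, and the
fold changes versus the parent.  Writes results/rate_table.tsv and
results/fold_changes.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RESULTS  # noqa: E402

from genreduce.fermentation import fold_change, rate_table  # noqa: E402
from genreduce.published import (  # noqa: E402
    FERMENTATION_WINDOW,
    MOLAR_PRODUCTION_RATES,
    OHPHZ_TITERS_MG_L,
    SPECIFIC_GROWTH_RATES,
)
from genreduce.simulate import FermSimConfig, generate_fermentation  # noqa: E402


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    series = {}
    for strain, mu in SPECIFIC_GROWTH_RATES.items():
        cfg = FermSimConfig(strain=strain, mu_true=mu, q_true=MOLAR_PRODUCTION_RATES[strain])
        series[strain] = generate_fermentation(cfg)[0]
    table = rate_table(series, FERMENTATION_WINDOW)
    table.to_csv(RESULTS / "rate_table.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    parent = "GP72(rpeA-)"
    folds = []
    for strain in SPECIFIC_GROWTH_RATES:
        if strain == parent:
            continue
        for analyte in ("PCA", "2OHPCA", "2OHPHZ"):
            folds.append(
                dict(
                    strain=strain,
                    quantity=f"q_{analyte}",
                    fold_vs_parent=round(
                        fold_change(
                            MOLAR_PRODUCTION_RATES[strain][analyte],
                            MOLAR_PRODUCTION_RATES[parent][analyte],
                        ),
                        1,
                    ),
                )
            )
        folds.append(
            dict(
                strain=strain,
                quantity="titer_2OHPHZ",
                fold_vs_parent=round(
                    fold_change(OHPHZ_TITERS_MG_L[strain], OHPHZ_TITERS_MG_L[parent]), 1
                ),
            )
        )
    fold_df = pd.DataFrame(folds)
    fold_df.to_csv(RESULTS / "fold_changes.tsv", sep="\t", index=False)
    print(fold_df.to_string(index=False))
    print(f"wrote {RESULTS/'rate_table.tsv'} and {RESULTS/'fold_changes.tsv'}")


if __name__ == "__main__":
    main()
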