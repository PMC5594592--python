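"""Design markerless-deletion constructs for every planned region.

For each region: two homology arms abutting the deletion endpoints,
overlap-extension primers F1/R1/F2/R2 (18-20 bp junction overlap,
restriction sites absent from the insert), and NF/NR verification
primers whose template is lost once the deletion is made.  Writes
results/primers.tsv and reports the simulated overlap-PCR check.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RESULTS, build_plan, get_bundle, load_classification  # noqa: E402

from genreduce.constructs import design_arms, design_primers, simulate_overlap_pcr  # noqa: E402


def main() -> None:
    bundle = get_bundle()
    plan = build_plan(bundle, load_classification())
    rows = []
    for region in plan.regions:
        arms = design_arms(bundle.target, region.interval)
        primers = design_primers(arms, region.interval, bundle.target)
        assembled = simulate_overlap_pcr(arms, primers)
        exact = assembled == arms.upstream_arm + arms.downstream_arm
        print(
            f"{region.name}: arms {len(arms.upstream_arm)}+{len(arms.downstream_arm)} bp, "
            f"overlap {primers.overlap_len} bp, sites {primers.sites}, "
            f"overlap-PCR exact: {exact}"
        )
        for p in primers:
            rows.append(
                dict(
                    region=region.name,
                    primer=p.name,
                    sequence=p.sequence,
                    length=len(p.sequence),
                    tm_c=round(p.tm, 1),
                    strand=p.strand,
                    start=p.start,
                    end=p.end,
                )
            )
    pd.DataFrame(rows).to_csv(RESULTS / "primers.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS/'primers.tsv'} ({len(rows)} primers)")


if __name__ == "__main__":
    main()
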