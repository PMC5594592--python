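"""Select candidate deletion regions from the classified gene table.

Takes maximal runs of strain-specific, non-essential genes, snaps the
endpoints to intergenic midpoints, and keeps runs spanning >= 15 kb with
>= 11 genes.  Writes results/deletion_plan.tsv and
results/deletion_plan.bed.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RESULTS, build_plan, get_bundle, load_classification  # noqa: E402

from genreduce.genome_model import write_bed  # noqa: E402
from genreduce.regions import plan_table  # noqa: E402


def main() -> None:
    bundle = get_bundle()
    statuses = load_classification()
    plan = build_plan(bundle, statuses)
    table = plan_table(plan)
    table.to_csv(RESULTS / "deletion_plan.tsv", sep="\t", index=False)
    write_bed(
        [r.interval for r in plan.regions], RESULTS / "deletion_plan.bed", bundle.target.name
    )
    print(table.to_string(index=False))
    print(
        f"{len(plan.regions)} region(s), {plan.total_bp:,} bp "
        f"({100 * plan.total_bp / bundle.target.length:.2f}% of the genome)"
    )
    print(f"wrote {RESULTS/'deletion_plan.tsv'} and {RESULTS/'deletion_plan.bed'}")


if __name__ == "__main__":
    main()
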