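"""Apply the deletion plan and account for it in a cumulative ledger.

Writes results/deletion_ledger.tsv (one row per sequential deletion with
cumulative bp and percent of the parent genome) plus
results/deleted_regions.bed, and — as a cross-check of the ledger
arithmetic itself — results/published_ledger.tsv, the 22-step reduction
series of P. chlororaphis GP72(rpeA-) recomputed from its per-step sizes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RESULTS, build_plan, get_bundle, load_classification  # noqa: E402

from genreduce.genome_model import write_bed  # noqa: E402
from genreduce.ledger import apply_plan, ledger_from_step_sizes, ledger_table  # noqa: E402
from genreduce.published import DELETION_STEPS, PARENT_GENOME_BP  # noqa: E402


def main() -> None:
    bundle = get_bundle()
    plan = build_plan(bundle, load_classification())
    reduced, rows, lift = apply_plan(bundle.target, plan)
    ledger_table(rows).to_csv(RESULTS / "deletion_ledger.tsv", sep="\t", index=False)
    write_bed(lift.intervals, RESULTS / "deleted_regions.bed", bundle.target.name)
    print(ledger_table(rows).to_string(index=False))
    print(f"reduced genome: {reduced.length:,} bp (parent {bundle.target.length:,} bp)")

    pub = ledger_from_step_sizes(
        [bp for bp, _, _ in DELETION_STEPS],
        PARENT_GENOME_BP,
        loci=[loci for _, loci, _ in DELETION_STEPS],
        descriptions=[d for _, _, d in DELETION_STEPS],
    )
    ledger_table(pub).to_csv(RESULTS / "published_ledger.tsv", sep="\t", index=False)
    final = pub[-1]
    print(
        f"published series: {len(pub)} steps, {final.cumulative_deletion_bp:,} bp "
        f"({final.cumulative_percent}%), reduced genome "
        f"{PARENT_GENOME_BP - final.cumulative_deletion_bp:,} bp"
    )
    print(f"wrote {RESULTS/'deletion_ledger.tsv'} and {RESULTS/'published_ledger.tsv'}")


if __name__ == "__main__":
    main()
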