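"""Generate the seeded synthetic inputs and record their ground truth.

Writes results/annotation.tsv (gene coordinates of the simulated target
genome) and results/truth.tsv (which genes are conserved, essential, or
part of a planted deletable region).  The sequences themselves are not
persisted; every later script regenerates them deterministically from
the same seed.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RESULTS, SEED, get_bundle  # noqa: E402


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    bundle = get_bundle()
    genome = bundle.target
    rows = [
        dict(
            locus_tag=g.locus_tag,
            start=g.start,
            end=g.end,
            strand=g.strand,
            length_bp=g.end - g.start + 1,
        )
        for g in genome.genes
    ]
    import pandas as pd

    pd.DataFrame(rows).to_csv(RESULTS / "annotation.tsv", sep="\t", index=False)
    bundle.truth.to_csv(RESULTS / "truth.tsv", sep="\t", index=False)

    n_cons = int(bundle.truth["conserved"].sum())
    n_ess = int(bundle.truth["essential"].sum())
    n_region = int(bundle.truth["region"].fillna("").ne("").sum())
    print(f"seed {SEED}: simulated genome {genome.length:,} bp, {len(genome.genes)} genes")
    print(f"  conserved {n_cons}, essential {n_ess}, planted-region genes {n_region}")
    print(f"wrote {RESULTS/'annotation.tsv'} and {RESULTS/'truth.tsv'}")


if __name__ == "__main__":
    main()
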