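"""Shared constants and helpers for the numbered analysis scripts.

Each script regenerates the simulated inputs from SEED (generation is
deterministic and cheap) and passes intermediate tables through the
results/ directory, so the scripts can be run one by one in order.
"""

from pathlib import Path

import pandas as pd

from genreduce.regions import RegionCriteria, filter_regions, find_candidate_runs, order_plan
from genreduce.simulate import GenomeSimConfig, generate_genome_pair

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def get_bundle():
    """The seeded synthetic genome pair used throughout the analysis."""
    return generate_genome_pair(GenomeSimConfig(seed=SEED))


def load_classification() -> pd.DataFrame:
    path = RESULTS / "classification.tsv"
    if not path.exists():
        raise SystemExit(f"{path} missing -- run analysis/02_classify_genes.py first")
    return pd.read_csv(path, sep="\t")


def build_plan(bundle, statuses):
    runs = find_candidate_runs(statuses, bundle.target)
    regions = filter_regions(runs, RegionCriteria(), bundle.target, statuses=statuses)
    return order_plan(regions, bundle.target.length)
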