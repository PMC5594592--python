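# genreduce

Design and book-keeping toolkit for genome reduction of a phenazine-producing
*Pseudomonas chlororaphis* chassis.

## Scientific problem

Large fractions of a bacterial genome are dispensable under bioprocess
conditions: prophages, secondary-metabolite clusters, transporters for
environments a fermenter never presents.  Deleting them can free carbon and
energy for a product of interest — here the phenazines PCA
(phenazine-1-carboxylic acid), 2-OH-PCA and 2-OH-PHZ — but only if every
deletion avoids essential genes and the strain's construction and outcome are
tracked rigorously.  This package implements that workflow end to end:

1. **Gene classification** (`genreduce.classify`, `genreduce.alignment`) —
   in-silico subtractive hybridization against a reference proteome using exact
   Smith–Waterman local alignment with Karlin–Altschul statistics.  A gene is
   *conserved* when its homology value `H = (identity/100) · min(1,
   aln_len/qlen)` reaches 0.42 with E < 1e-5; it is *essential* when at least
   8 of 15 essential-gene panels report a hit with ≥ 35 % identity and
   E ≤ 1e-10.
2. **Deletion-region selection** (`genreduce.regions`) — maximal runs of
   strain-specific, non-essential genes spanning ≥ 15 kb with ≥ 11 genes,
   endpoints snapped to intergenic midpoints, curated clusters supported,
   prioritized secondary-metabolite → metabolism/transport → hypothetical.
3. **Deletion ledger** (`genreduce.ledger`) — sequential application of the
   plan with exact cumulative bp/percent accounting and coordinate liftover
   from parent to reduced genome.
4. **Construct design** (`genreduce.constructs`) — markerless-deletion
   (pK18mobsacB-style) designs: homology arms abutting the deletion endpoints,
   overlap-extension primers F1/R1/F2/R2 with an 18–20 bp junction overlap,
   restriction sites chosen to be absent from the insert, and NF/NR
   verification primers whose template disappears with the deletion.
   Nearest-neighbor melting temperatures throughout.
5. **Fermentation kinetics** (`genreduce.fermentation`) — specific growth rate
   μ, molar phenazine production rates q (mmol · g⁻¹ · h⁻¹), mass-basis total
   rates, and fold changes over the production window.
6. **Synthetic data** (`genreduce.simulate`) — seeded generators for genome
   pairs with planted truth (conservation, essentiality, deletable regions)
   and for fermentation courses with known kinetic parameters, used for
   validation.

The reported inputs for the 22-step *P. chlororaphis* GP72(rpeA-) reduction
series (per-step sizes, molar rates, titers) live in `genreduce.published`;
every derived number is recomputed at run time.

## Worked example

Recompute the cumulative accounting of the published 22-step deletion series:

```python
from genreduce.ledger import ledger_from_step_sizes, ledger_table
from genreduce.published import DELETION_STEPS, PARENT_GENOME_BP

rows = ledger_from_step_sizes([bp for bp, _, _ in DELETION_STEPS], PARENT_GENOME_BP)
print(ledger_table(rows).tail(3).to_string(index=False))
final = rows[-1]
print(f"total deleted: {final.cumulative_deletion_bp:,} bp "
      f"({final.cumulative_percent}% of {PARENT_GENOME_BP:,} bp); "
      f"reduced genome {PARENT_GENOME_BP - final.cumulative_deletion_bp:,} bp")
```

prints

```
mutant  multiple_deletion_bp  cumulative_deletion_bp cumulative_deletion_percent genomic_loci description
 MDS20                 56152                  616537                        9.25
 MDS21                 40441                  656978                        9.86
 MDS22                 28772                  685750                       10.29
total deleted: 685,750 bp (10.29% of 6,663,241 bp); reduced genome 5,977,491 bp
```

and the kinetics of the best producer:

```python
from genreduce.fermentation import total_phenazine_mass_rate, fold_change, round_sig
from genreduce.published import MOLAR_PRODUCTION_RATES

parent = MOLAR_PRODUCTION_RATES["GP72(rpeA-)"]
mds10 = MOLAR_PRODUCTION_RATES["MDS10"]
print("parent total mass rate:", round_sig(total_phenazine_mass_rate(parent), 2), "g/g/h")
print("MDS10  total mass rate:", round_sig(total_phenazine_mass_rate(mds10), 2), "g/g/h")
print("PCA rate fold change  :", round(fold_change(mds10["PCA"], parent["PCA"]), 1))
```

prints

```
parent total mass rate: 0.0031 g/g/h
MDS10  total mass rate: 0.0056 g/g/h
PCA rate fold change  : 3.3
```

## Command line

The `genreduce` entry point exposes the stages individually
(`simulate`, `classify`, `select-regions`, `ferment-rates`) and as a whole
(`run-all` from a YAML config).  See `genreduce --help`.

## Repository layout

- `src/genreduce/` — the library.
- `analysis/` — numbered scripts that run the full analysis on a seeded
  synthetic genome and on the published input tables, writing all tables to
  `results/`.  Run them in order:

  ```sh
  python analysis/01_simulate_inputs.py
  python analysis/02_classify_genes.py     # ~90 s: exact all-vs-all alignment
  python analysis/03_select_regions.py
  python analysis/04_apply_deletions.py
  python analysis/05_design_constructs.py
  python analysis/06_fermentation_rates.py
  ```

- `results/` — tabular outputs (classification, deletion plan/ledger, primers,
  rate and fold-change tables).
- `tests/` — unit and acceptance tests, including independent oracles
  (exhaustive alignment DP, brute-force region enumeration, Runge–Kutta
  integration) the implementation is checked against.
- `scripts/acceptance.py` — recomputes the headline quantities and writes them
  as JSON.

## Reproduction

```sh
pip install -e .
python -m pytest -q tests/                       # full test suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
for s in analysis/0*.py; do python "$s"; done    # regenerate results/
```

All computations are deterministic given the seed; the analysis scripts use
seed 1 throughout.
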