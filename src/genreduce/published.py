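"""Reported input tables for the P. chlororaphis GP72(rpeA-) deletion series.

These are the published step sizes, loci and fermentation rates of the
22-step multiple-deletion series (MDS1-MDS22) derived from strain GP72;
the package's ledger and kinetics code recomputes every derived quantity
(cumulative bp, cumulative percent, mass-basis rates, fold changes) from
these inputs at run time.
"""

from __future__ import annotations

PARENT_GENOME_BP = 6_663_241

# (step deletion bp, genomic loci, description) in series order MDS1..MDS22
DELETION_STEPS: list[tuple[int, str, str]] = [
    (14_022, "MOK_02716-MOK_02727", "achromobactin operon"),
    (21_614, "MOK_04727-MOK_04735", "P. fluorescens insecticidal toxin operon"),
    (48_164, "MOK_01688-MOK_01707", "part of pvd operon"),
    (2_548, "MOK_04926-MOK_04927", "hydrogen cyanide operon"),
    (6_726, "MOK_04030-MOK_04036", "pyrrolnitrin operon"),
    (19_167, "MOK_00110-MOK_00130", "includes ccdA, azlC, tdcB, gss, mgtA"),
    (41_371, "MOK_00373-MOK_00408", "includes ltaA, gbcAB, proXWV, betTIBA"),
    (18_221, "MOK_00955-MOK_00974", "includes aurF, fabGZF, acpP, psyIR, ada"),
    (24_416, "MOK_00497-MOK_00507", "includes pvdL, pvdS, atuR, atuA"),
    (38_000, "MOK_00047-MOK_00091", "includes ligT, mmsB, araD, hyi, folA"),
    (26_771, "MOK_01641-MOK_01663", "includes katG, vgrG, gstA, amiE, surE"),
    (37_633, "MOK_01720-MOK_01754", "includes str, pea operon, aphA_2, mrdA_1"),
    (37_411, "MOK_01897-MOK_01932", "includes matP, wbp operon, lpd3, cdsA_2"),
    (29_156, "MOK_02207-MOK_02237", "includes hisPMQJ, dam"),
    (24_108, "MOK_02626-MOK_02642", "includes dmpA, apr operon, pspAB, pueBA"),
    (28_273, "MOK_02657-MOK_02685", "includes ssuBCA, aidB, uspA, puuC, dehII"),
    (87_173, "MOK_02743-MOK_02813", "includes fabG, idnO, aofH, aidB, phoD, aofH"),
    (26_866, "MOK_02690-MOK_02714", "includes gabT, narL, glnA_3, plcN, FecR"),
    (28_745, "MOK_03695-MOK_03722", "mostly related to hypothetical protein"),
    (56_152, "MOK_05764-MOK_05802", "mostly related to hypothetical protein"),
    (40_441, "MOK_01057-MOK_01097", "czcABCRD and genes with unknown function"),
    (28_772, "MOK_00230-MOK_00246", "mostly encoding hypothetical protein"),
]

# reported cumulative percent per step (2 dp), for cross-checking the ledger
REPORTED_CUMULATIVE_PERCENT: list[float] = [
    0.21, 0.53, 1.26, 1.30, 1.40, 1.68, 2.31, 2.58, 2.95, 3.52, 3.92,
    4.48, 5.04, 5.48, 5.84, 6.27, 7.58, 7.98, 8.41, 9.25, 9.86, 10.29,
]

# fermentation window (h) and per-strain molar production rates (mmol/g/h)
FERMENTATION_WINDOW: tuple[float, float] = (14.0, 24.0)

SPECIFIC_GROWTH_RATES: dict[str, float] = {
    "GP72(rpeA-)": 0.1226,
    "MDS10": 0.0601,
    "MDS22": 0.0314,
}

MOLAR_PRODUCTION_RATES: dict[str, dict[str, float]] = {
    "GP72(rpeA-)": {"PCA": 0.0061, "2OHPCA": 0.0064, "2OHPHZ": 0.0008},
    "MDS10": {"PCA": 0.0202, "2OHPCA": 0.0015, "2OHPHZ": 0.0035},
    "MDS22": {"PCA": 0.0076, "2OHPCA": 0.0025, "2OHPHZ": 0.0092},
}

# 2-OH-PHZ titers after 24 h of cultivation (mg/L)
OHPHZ_TITERS_MG_L: dict[str, float] = {
    "GP72(rpeA-)": 22.2,
    "MDS10": 98.3,
    "MDS22": 99.1,
}
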