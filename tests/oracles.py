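"""Independent brute-force oracles used only by the tests.

These are written against the problem statements, not against the package
implementation, so that agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Full O(nm) affine-gap local alignment score (Gotoh recurrences).

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    first = gap_open + gap_extend  # cost of opening a 1-residue gap
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_qualifying_runs(genome, statuses, min_genes: int):
    """All maximal runs of deletable genes with >= min_genes, by brute scan.

    Deletable = strain_specific and not essential.  Returns lists of locus
    tags.
    """
    deletable = {
        row["locus_tag"]: row["conservation"] == "strain_specific"
        and not bool(row["essential"])
        for _, row in statuses.iterrows()
    }
    loci = [g.locus_tag for g in genome.genes]
    runs, cur = [], []
    for locus in loci:
        if deletable[locus]:
            cur.append(locus)
        else:
            if len(cur) >= min_genes:
                runs.append(cur)
            cur = []
    if len(cur) >= min_genes:
        runs.append(cur)
    return runs


def rk4_phenazine(t_grid, mu, q, x0, k, dt=0.01):
    """Fixed-step RK4 integration of the phenazine production ODEs (mmol/L)."""

    def deriv(t, p):
        x = x0 * np.exp(mu * t)
        return np.array(
            [
                q.get("PCA", 0.0) * x,
                q.get("2OHPCA", 0.0) * x - k * p[1],
                q.get("2OHPHZ", 0.0) * x + k * p[1],
            ]
        )

    p = np.zeros(3)
    t = 0.0
    targets = sorted(float(x) for x in t_grid)
    results = []
    for target in targets:
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1 = deriv(t, p)
            k2 = deriv(t + h / 2, p + h / 2 * k1)
            k3 = deriv(t + h / 2, p + h / 2 * k2)
            k4 = deriv(t + h, p + h * k3)
            p = p + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        results.append(p.copy())
    arr = np.array(results)
    return {"PCA": arr[:, 0], "2OHPCA": arr[:, 1], "2OHPHZ": arr[:, 2]}
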