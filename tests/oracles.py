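"""Independent reference implementations used only to check the package.

Everything here is deliberately written by a different route than the
library code it validates: dense GLS instead of mixed-model equations,
memoized kinship recursion instead of the tabular loop, Monte-Carlo gene
drop instead of expected relationships, and closed-form ANOVA moments
instead of REML.
"""

from __future__ import annotations

import numpy as np

UNKNOWN = "0"


def gls_mixed_model(y, X, Z_list, G_list, sigma2_list, sigma2_e):
    """Direct generalized-least-squares solve of a mixed model.

    V = sum_k s2_k Z_k G_k Z_k' + s2_e I; beta = (X'V^-1X)^-1 X'V^-1 y;
    u_k = s2_k G_k Z_k' V^-1 (y - X beta). Returns (beta, [u_k]).
    """
    y = np.asarray(y, float)
    n = y.size
    V = sigma2_e * np.eye(n)
    for Z, G, s2 in zip(Z_list, G_list, sigma2_list):
        G = np.eye(Z.shape[1]) if G is None else G
        V += s2 * Z @ G @ Z.T
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    resid = Vinv @ (y - X @ beta)
    us = []
    for Z, G, s2 in zip(Z_list, G_list, sigma2_list):
        G = np.eye(Z.shape[1]) if G is None else G
        us.append(s2 * G @ Z.T @ resid)
    return beta, us


def kinship_recursive(records):
    """Kinship matrix by top-down recursion over (id, sire, dam) triples.

    theta(i,i) = 0.5 (1 + theta(s_i, d_i)); theta(i,j) for i later than j is
    0.5 (theta(s_i, j) + theta(d_i, j)); unknown parents contribute 0.
    Additive relationship = 2 theta.
    """
    parents = {r[0]: (r[1], r[2]) for r in records}
    order = {r[0]: k for k, r in enumerate(records)}
    cache: dict = {}

    def theta(i, j):
        if i == UNKNOWN or j == UNKNOWN:
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        si, di = parents[i]
        if i == j:
            val = 0.5 * (1.0 + theta(si, di))
        else:
            val = 0.5 * (theta(si, j) + theta(di, j))
        cache[key] = val
        return val

    ids = [r[0] for r in records]
    n = len(ids)
    A = np.empty((n, n))
    for a, i in enumerate(ids):
        for b, j in enumerate(ids):
            A[a, b] = 2.0 * theta(i, j)
    return ids, A


def gene_drop_relationship(records, n_drops: int, seed: int):
    """Monte-Carlo IBD-based additive relationships.

    Founders receive unique allele labels; alleles are dropped through the
    pedigree with fair coin inheritance per drop. The estimated additive
    relationship between i and j is twice the probability that one allele
    drawn at random from each is identical by descent.
    """
    rng = np.random.default_rng(seed)
    ids = [r[0] for r in records]
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    alleles = np.zeros((n, 2, n_drops), dtype=np.int64)
    next_label = 1
    for r, (iid, sire, dam) in enumerate(records):
        for side, parent in enumerate((sire, dam)):
            if parent == UNKNOWN:
                alleles[r, side, :] = next_label
                next_label += 1
            else:
                p = index[parent]
                pick = rng.integers(2, size=n_drops)
                alleles[r, side, :] = alleles[p, pick, np.arange(n_drops)]
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            # mean IBD probability of one random allele from each side
            share = 0.0
            for a in range(2):
                for b in range(2):
                    share += np.mean(alleles[i, a] == alleles[j, b])
            A[i, j] = A[j, i] = share / 2.0
    return ids, A


def anova_oneway_family(y, fam_labels):
    """Balanced one-way ANOVA method-of-moments variance components.

    Returns (between-family component, within-family component); requires a
    balanced design.
    """
    y = np.asarray(y, float)
    fams, inv = np.unique(np.asarray(fam_labels), return_inverse=True)
    k = fams.size
    counts = np.bincount(inv)
    if np.ptp(counts) != 0:
        raise ValueError("ANOVA oracle needs a balanced design")
    m = counts[0]
    means = np.array([y[inv == i].mean() for i in range(k)])
    grand = y.mean()
    msb = m * np.sum((means - grand) ** 2) / (k - 1)
    msw = sum(np.sum((y[inv == i] - means[i]) ** 2) for i in range(k)) / (k * (m - 1))
    return (msb - msw) / m, msw
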