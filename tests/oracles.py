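"""Independent brute-force oracles used by the test suite.

These deliberately use plain loops and closed forms, independent of the
package's vectorized implementations.
"""

import itertools

import numpy as np


def exhaustive_celltype_p(X, gene_ids, types, db_pairs):
    """Exact permutation p over all distinct type-label reassignments.

    Enumerates every distinct assignment of the observed label multiset to
    cells, computes the product interaction score per assignment with plain
    loops, and returns p = fraction of assignments with score >= observed,
    keyed by (sender, receiver, ligand, receptor).
    """
    X = np.asarray(X, dtype=float)
    genes = {g: j for j, g in enumerate(gene_ids)}
    labels = sorted(set(types))
    n = len(types)

    def score(assign, sender, receiver, lig, rec):
        lcells = [i for i in range(n) if assign[i] == sender]
        rcells = [i for i in range(n) if assign[i] == receiver]
        lmean = sum(X[i, genes[lig]] for i in lcells) / len(lcells)
        rmean = sum(X[i, genes[rec]] for i in rcells) / len(rcells)
        return lmean * rmean

    assignments = sorted(set(itertools.permutations(types)))
    out = {}
    for lig, rec in db_pairs:
        for s in labels:
            for r in labels:
                obs = score(types, s, r, lig, rec)
                ge = sum(score(a, s, r, lig, rec) >= obs for a in assignments)
                out[(s, r, lig, rec)] = ge / len(assignments)
    return out


def step_up_bh(p):
    """Benjamini-Hochberg step-up adjusted p-values, plain-loop reference."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
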