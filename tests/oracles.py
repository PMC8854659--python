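"""Independent reference implementations used as test oracles.

Everything here is deliberately written against a different code path
than the package: likelihoods by exhaustive ancestral-state enumeration
with dense scipy matrix exponentials, FDR via statsmodels, Welch tests
via scipy/statsmodels.  Nothing imports the package's engines.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm

BASES = "ACGT"


def enumeration_log_likelihood(model, column: dict[str, str],
                               s: float = 1.0, rho: float = 1.0,
                               subtree: frozenset | None = None) -> float:
    """Column log-likelihood by brute-force sum over ancestral states.

    ``model`` is a package ``NeutralModel``; only its plain data (tree
    topology, branch lengths, pi, Q) is read.  Missing leaves ('-'/'N'
    or absent from ``column``) are marginalized by summing over their
    states too.
    """
    nodes = list(model.tree.postorder())
    root = nodes[-1]
    scaled_ids: set[int] = set()
    if subtree:
        scaled_ids = {id(n) for n in model.tree.clade_nodes(subtree)}
    pi = model.subst.freqs
    q = model.subst.rate_matrix

    free = []      # nodes we sum over: internal nodes + missing leaves
    fixed = {}     # node-id -> observed state
    for n in nodes:
        if n.is_leaf:
            ch = column.get(n.name, "-")
            if ch in "-Nn":
                free.append(n)
            else:
                fixed[id(n)] = BASES.index(ch)
        else:
            free.append(n)

    pmat = {}
    for n in nodes[:-1]:
        t = n.length * s * (rho if id(n) in scaled_ids else 1.0)
        pmat[id(n)] = expm(q * t)

    total = 0.0
    for assign in itertools.product(range(4), repeat=len(free)):
        state = dict(fixed)
        state.update({id(n): a for n, a in zip(free, assign)})
        prob = pi[state[id(root)]]
        for n in nodes[:-1]:
            prob *= pmat[id(n)][state[id(n.parent)], state[id(n)]]
        total += prob
    return math.log(total) if total > 0 else -math.inf


def bh_reference(pvals) -> np.ndarray:
    """BH step-up via statsmodels (independent of the package's own)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(pvals, dtype=float),
                         method="fdr_bh")[1]


def welch_reference(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch t, df and upper-tail p via explicit textbook formulas."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    from scipy.stats import t as tdist
    return t, df, float(tdist.sf(t, df))
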