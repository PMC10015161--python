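"""Shared independent oracles for the test suite."""

import itertools

import numpy as np


def brute_force_site_lik(tree, msa, model):
    """Independent oracle: explicit sum over all ancestral-state assignments."""
    pat, _ = msa.patterns
    leaves = tree.leaves()
    internal = [v for v in tree.postorder() if not v.is_leaf]
    rates = model.category_rates()
    allow = lambda c: np.eye(20)[c] if c < 20 else np.ones(20)
    liks = np.zeros(pat.shape[1])
    row_of = {l: i for i, l in enumerate(msa.labels)}
    for p in range(pat.shape[1]):
        var_lik = 0.0
        for r in rates:
            total = 0.0
            for states in itertools.product(range(20), repeat=len(internal)):
                assign = {id(v): s for v, s in zip(internal, states)}
                term = model.freqs[assign[id(tree.root)]]
                for v in tree.postorder():
                    if v is tree.root:
                        continue
                    parent = next(u for u in tree.postorder()
                                  if v in u.children)
                    pm = model.transition_matrix(v.length, r)
                    if v.is_leaf:
                        obs = allow(pat[row_of[v.label], p])
                        term *= (pm[assign[id(parent)]] * obs).sum()
                    else:
                        term *= pm[assign[id(parent)], assign[id(v)]]
                total += term
            var_lik += total / model.k
        lik = (1 - model.p_inv) * var_lik
        if model.p_inv > 0:
            a = np.ones(20)
            for v in leaves:
                a *= allow(pat[row_of[v.label], p])
            lik += model.p_inv * (a @ model.freqs)
        liks[p] = lik
    return liks


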