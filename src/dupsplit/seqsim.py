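"""Simulation of amino-acid alignments along a tree, and gene-family fixtures.

The generator draws from exactly the model family the likelihood module
fits (reversible exchangeability model, proportion of invariant sites,
k discrete gamma rate categories), so parameter-recovery experiments
compare like with like.  Each column independently: with probability
``p_inv`` it is invariant (a single equilibrium draw copied to every
leaf); otherwise it gets one of the k category rates uniformly at random
and states evolve down the tree through the transition kernel for
(branch length x category rate).  Gaps are never simulated.

:func:`make_gene_family_fixture` builds the six-OTU vitellogenin-style
study system: osteichthyan VTG1/VTG2, chondrichthyan VTG1/VTG2,
cyclostome VTG, and an outgroup, generated under either duplication-
timing scenario:

* ``post_split`` — the VTG1/VTG2 duplications happened after the
  Chondrichthyes-Osteichthyes split, so each lineage's paralogs are
  sisters: ``((Ost-1,Ost-2),(Cho-1,Cho-2))`` next to Cyc and OG.
* ``pre_split`` — one duplication preceded the split, so orthologs
  pair across lineages: ``((Ost-1,Cho-1),(Ost-2,Cho-2))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .phylolik import MSA, SubstModel, discrete_gamma_rates
from .treespace import OTUConstraint, Node, Tree, TreeError, parse_newick

__all__ = [
    "SimSpec",
    "ScenarioSpec",
    "simulate_alignment",
    "make_gene_family_fixture",
    "DEFAULT_OTUS",
    "scenario_supertree",
    "simspec_to_json",
    "simspec_from_json",
    "scenariospec_to_json",
    "scenariospec_from_json",
]

DEFAULT_OTUS = ("Ost-1", "Ost-2", "Cho-1", "Cho-2", "Cyc", "OG")

#: supertree shapes over the six OTUs for each duplication-timing scenario
_SCENARIO_NEWICK = {
    "post_split": "(((Ost-1,Ost-2),(Cho-1,Cho-2)),Cyc,OG);",
    "pre_split": "(((Ost-1,Cho-1),(Ost-2,Cho-2)),Cyc,OG);",
}


@dataclass
class SimSpec:
    """Everything that determines one simulated alignment."""

    tree: Tree
    model: SubstModel
    n_sites: int = 1195
    seed: int = 0

    def validate(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        leaves = self.tree.leaf_labels()
        if not leaves:
            raise ValueError("tree has no leaves")
        for v in self.tree.postorder()[:-1]:
            if v.length is None or not np.isfinite(v.length) or v.length < 0:
                raise ValueError(
                    f"simulation tree needs finite non-negative branch lengths, "
                    f"got {v.length}")


def _sample_markov(parent_states: np.ndarray, p: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per site from the transition rows of *p*."""
    cum = np.cumsum(p, axis=1)
    u = rng.random(parent_states.shape[0])
    return (cum[parent_states] < u[:, None]).sum(axis=1).astype(np.int8)


def simulate_alignment(spec: SimSpec) -> MSA:
    """Simulate an alignment under *spec*; the seed fully determines the output."""
    spec.validate()
    model, n = spec.model, spec.n_sites
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    invariant = rng.random(n) < model.p_inv
    root_states = rng.choice(20, size=n, p=model.freqs).astype(np.int8)
    n_var = int((~invariant).sum())
    cats = rng.integers(0, model.k, size=n_var)
    rates = model.category_rates()

    var_idx = np.flatnonzero(~invariant)
    nodes = spec.tree.postorder()
    states = {id(nodes[-1]): root_states[var_idx]}
    # preorder: parents before children
    for v in reversed(nodes):
        for c in v.children:
            child = np.empty(n_var, dtype=np.int8)
            for k in range(model.k):
                sel = cats == k
                if not sel.any():
                    continue
                p = model.transition_matrix(c.length, rates[k])
                p = p / p.sum(axis=1, keepdims=True)
                child[sel] = _sample_markov(states[id(v)][sel], p, rng)
            states[id(c)] = child

    labels, rows = [], []
    for leaf in spec.tree.leaves():
        row = root_states.copy()
        row[var_idx] = states[id(leaf)]
        labels.append(leaf.label)
        rows.append(row)
    return MSA(labels, np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------
# Six-OTU gene-family fixtures
# ---------------------------------------------------------------------

def _default_leaf_counts():
    return {otu: 2 for otu in DEFAULT_OTUS}


@dataclass
class ScenarioSpec:
    """Study conditions for a synthetic six-OTU gene-family alignment.

    Branch lengths are in expected substitutions/site.  ``dup_branch``
    is the internal branch created by the gene duplication,
    ``split_branch`` the internal branch created by the lineage split;
    together they set how much signal separates the two scenarios.
    ``stem_branch`` is each OTU's stem, ``within_branch`` the terminal
    branches inside an OTU's fixed subtree.
    """

    scenario: str = "post_split"
    leaf_counts: dict = field(default_factory=_default_leaf_counts)
    dup_branch: float = 0.12
    split_branch: float = 0.12
    stem_branch: float = 0.25
    within_branch: float = 0.1
    model: SubstModel = None
    n_sites: int = 1195
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in _SCENARIO_NEWICK:
            raise ValueError(
                f"scenario must be one of {sorted(_SCENARIO_NEWICK)}, "
                f"got {self.scenario!r}")
        if self.model is None:
            self.model = SubstModel.jtt(alpha=1.0, k=4, p_inv=0.1)
        bad = {o: c for o, c in self.leaf_counts.items() if c < 1}
        if bad or set(self.leaf_counts) != set(DEFAULT_OTUS):
            raise ValueError(
                f"leaf_counts must give every OTU {DEFAULT_OTUS} a count >= 1, "
                f"got {self.leaf_counts}")


def _model_to_json(model: SubstModel) -> dict:
    if model.name not in ("JTT", "Poisson"):
        raise ValueError("only the named built-in models serialize to JSON")
    return {"name": model.name, "alpha": model.alpha, "k": model.k,
            "p_inv": model.p_inv}


def _model_from_json(d: dict) -> SubstModel:
    maker = {"JTT": SubstModel.jtt, "Poisson": SubstModel.poisson}
    return maker[d["name"]](alpha=d["alpha"], k=d["k"], p_inv=d["p_inv"])


def simspec_to_json(spec: SimSpec) -> str:
    """JSON form of a SimSpec (tree as Newick; built-in models only)."""
    return json.dumps({"tree": spec.tree.to_newick(),
                       "model": _model_to_json(spec.model),
                       "n_sites": spec.n_sites, "seed": spec.seed}, indent=2)


def simspec_from_json(text: str) -> SimSpec:
    d = json.loads(text)
    return SimSpec(tree=parse_newick(d["tree"]),
                   model=_model_from_json(d["model"]),
                   n_sites=d["n_sites"], seed=d["seed"])


def scenariospec_to_json(spec: ScenarioSpec) -> str:
    return json.dumps({
        "scenario": spec.scenario, "leaf_counts": spec.leaf_counts,
        "dup_branch": spec.dup_branch, "split_branch": spec.split_branch,
        "stem_branch": spec.stem_branch, "within_branch": spec.within_branch,
        "model": _model_to_json(spec.model),
        "n_sites": spec.n_sites, "seed": spec.seed}, indent=2)


def scenariospec_from_json(text: str) -> ScenarioSpec:
    d = json.loads(text)
    d["model"] = _model_from_json(d["model"])
    return ScenarioSpec(**d)


def scenario_supertree(scenario: str) -> Tree:
    """The generating six-OTU supertree (topology only) for a scenario."""
    return parse_newick(_SCENARIO_NEWICK[scenario])


def _otu_subtree(otu: str, n: int, within: float) -> str:
    """A pectinate within-OTU subtree over leaves '<otu>_a', '<otu>_b', ..."""
    names = [f"{otu}_{chr(ord('a') + i)}" for i in range(n)]
    if n == 1:
        return f"{names[0]};"
    s = f"{names[0]}:{within:g}"
    for nm in names[1:]:
        s = f"({s},{nm}:{within:g}):{within:g}"
    # the outermost length is the stem, set by the caller
    s = s[: s.rfind(":")]
    return s + ";"


def make_gene_family_fixture(spec: ScenarioSpec):
    """Simulate one gene-family dataset.

    Returns ``(msa, true_tree, constraint)``: the alignment, the full
    generating tree (with branch lengths), and the six-OTU constraint
    whose fixed within-OTU subtrees are the generating subtrees.
    """
    sup = scenario_supertree(spec.scenario)
    # internal branches: the cherry edges are duplication/split edges
    for v in sup.postorder():
        if v.is_leaf:
            v.length = spec.stem_branch
        elif v.length is None and v is not sup.root:
            v.length = spec.dup_branch if spec.scenario == "post_split" \
                else spec.split_branch
    # distinguish the deeper internal edge (joins the two cherries)
    for v in sup.root.children:
        if not v.is_leaf:
            v.length = spec.split_branch if spec.scenario == "post_split" \
                else spec.dup_branch

    otu_of, subtrees = {}, {}
    for otu in DEFAULT_OTUS:
        n = spec.leaf_counts[otu]
        subtrees[otu] = _otu_subtree(otu, n, spec.within_branch)
        for i in range(n):
            otu_of[f"{otu}_{chr(ord('a') + i)}"] = otu
    constraint = OTUConstraint(otu_of=otu_of, subtrees=subtrees)

    from .treespace import expand_constrained
    true_tree = expand_constrained(sup, constraint)

    sim = SimSpec(tree=true_tree, model=spec.model,
                  n_sites=spec.n_sites, seed=spec.seed)
    msa = simulate_alignment(sim)
    return msa, true_tree, constraint
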