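"""Duplication-timing scenario classification of six-OTU topologies.

Whether a gene duplication preceded or followed a lineage split leaves a
topological fingerprint on the gene tree collapsed to supertaxa.  For
the vitellogenin study system (osteichthyan VTG1/VTG2, chondrichthyan
VTG1/VTG2, cyclostome VTG, outgroup):

* ``post_split`` — duplications after the Chondrichthyes-Osteichthyes
  split: each lineage's two paralogs are sisters, so {Cho-1, Cho-2} and
  {Ost-1, Ost-2} are both clades when the tree is rooted on the
  outgroup.
* ``pre_split`` — the duplication preceded the split: a cross-lineage
  orthology clade appears instead ({Cho-1, Ost-1} or {Cho-2, Ost-2}).
  A single such pairing already forces the duplication before the
  split, so either clade suffices.
* ``other`` — topologies matching neither fingerprint.

Rules are data, not code: a :class:`RuleSet` is a priority-ordered list
of :class:`ScenarioRule` (all listed clades must be present; the first
matching rule wins), serializable as JSON so other gene families can
reuse the machinery with their own OTU scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .treespace import Tree, TreeError, clades_when_rooted_on

__all__ = [
    "ScenarioRule",
    "RuleSet",
    "default_vtg_rules",
    "classify_topology",
    "scenario_support",
    "OTHER",
]

OTHER = "other"


@dataclass(frozen=True)
class ScenarioRule:
    """One scenario fingerprint: every clade in ``required_clades`` must hold."""

    name: str
    required_clades: tuple

    def __post_init__(self):
        object.__setattr__(self, "required_clades",
                           tuple(frozenset(c) for c in self.required_clades))
        if not self.required_clades:
            raise ValueError("a rule needs at least one required clade")


@dataclass
class RuleSet:
    """Priority-ordered scenario rules over a fixed OTU name set."""

    otus: tuple
    outgroup: str
    rules: tuple

    def __post_init__(self):
        self.otus = tuple(self.otus)
        self.rules = tuple(self.rules)
        if self.outgroup not in self.otus:
            raise ValueError(f"outgroup {self.outgroup!r} not among OTUs")
        for rule in self.rules:
            for clade in rule.required_clades:
                if not clade <= set(self.otus):
                    raise ValueError(
                        f"rule {rule.name!r} references non-OTU names "
                        f"{sorted(clade - set(self.otus))}")
                if self.outgroup in clade:
                    raise ValueError(
                        f"rule {rule.name!r} puts the outgroup inside a clade")

    def to_json(self) -> str:
        return json.dumps({
            "otus": list(self.otus),
            "outgroup": self.outgroup,
            "rules": [{"name": r.name,
                       "required_clades": [sorted(c) for c in r.required_clades]}
                      for r in self.rules],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        d = json.loads(text)
        return cls(otus=tuple(d["otus"]), outgroup=d["outgroup"],
                   rules=tuple(ScenarioRule(r["name"],
                                            tuple(r["required_clades"]))
                               for r in d["rules"]))

    @classmethod
    def read(cls, path) -> "RuleSet":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


def default_vtg_rules() -> RuleSet:
    """The vitellogenin six-OTU rule set (post_split checked first)."""
    return RuleSet(
        otus=("Ost-1", "Ost-2", "Cho-1", "Cho-2", "Cyc", "OG"),
        outgroup="OG",
        rules=(
            ScenarioRule("post_split", ({"Cho-1", "Cho-2"}, {"Ost-1", "Ost-2"})),
            ScenarioRule("pre_split", ({"Cho-1", "Ost-1"},)),
            ScenarioRule("pre_split", ({"Cho-2", "Ost-2"},)),
        ),
    )


def classify_topology(tree: Tree, rules: RuleSet = None) -> str:
    """Scenario name of a six-OTU topology (``"other"`` on fall-through).

    The tree is rooted on the outgroup OTU; a rule matches when every
    one of its required leaf sets is a clade of that rooted tree.
    """
    if rules is None:
        rules = default_vtg_rules()
    leaves = set(tree.leaf_labels())
    if leaves != set(rules.otus):
        raise TreeError(
            f"topology leaves {sorted(leaves)} do not match the rule set's "
            f"OTUs {sorted(rules.otus)}")
    clades = clades_when_rooted_on(tree, rules.outgroup)
    for rule in rules.rules:
        if all(clade in clades for clade in rule.required_clades):
            return rule.name
    return OTHER


def scenario_support(table: pd.DataFrame, rules: RuleSet = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate a classified results table per scenario.

    Reports topology counts, the best (maximum) AU and KH p-values, how
    many topologies sit within one SE of the ML tree, and whether the
    scenario is rejected at level *alpha* (a scenario survives iff its
    best p_AU >= alpha).  Scenarios with no topologies get NaN support.
    """
    if rules is None:
        rules = default_vtg_rules()
    names = sorted({r.name for r in rules.rules}) + [OTHER]
    rows = []
    for name in names:
        sub = table[table["scenario"] == name]
        rows.append({
            "scenario": name,
            "n_topologies": len(sub),
            "best_p_au": sub["p_au"].max() if len(sub) else float("nan"),
            "best_p_kh": sub["p_kh"].max() if len(sub) else float("nan"),
            "n_within_1se": int(sub["within_1se"].sum()) if len(sub) else 0,
            "not_rejected": bool(sub["p_au"].max() >= alpha) if len(sub) else False,
        })
    return pd.DataFrame(rows)
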