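"""Merging of Boolean regulatory-network models.

Nodes are aligned across models by standardized gene symbol. A node with a
rule in two or more models is *overlapping*; its merged rule combines the
source rules under one of three deterministic semantics:

- ``OR``  — disjunction of the source rules: the node activates if any source
  model predicts activation (inclusive).
- ``AND`` — conjunction: the node activates only if every source model
  predicts activation (stringent).
- ``IW``  ("Inhibitor Wins") — the node is forced OFF whenever any regulator
  that acts as an inhibitor in *any* source rule is active; otherwise the OR
  combination applies. Constructed as
  ``(!i1 & !i2 & ...) & (rule1 | rule2 | ...)`` over the inhibitor union,
  which is pointwise equal to the piecewise definition.

Inhibitors are classified from the rules themselves (context-wise
monotonicity, see :func:`boolmerge.expr.classify_influence`), so IW works on
models that carry no edge-sign annotations. Non-monotone (DUAL) regulators
count as inhibitory by default; set ``dual_as_inhibitor=False`` to exclude
them, or pass ``sign_overrides`` to force signs from curation.

Nodes exclusive to one model are copied verbatim; nodes that appear in a
model only as an external input (no rule of their own) contribute no rule
and create no overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .errors import CapExceededError, MergeError
from .expr import (
    And,
    BoolExpr,
    InfluenceSign,
    Not,
    Or,
    Var,
    classify_influence,
    support,
)
from .model import LogicalModel, NodeSpec

__all__ = [
    "MergeConfig",
    "MergeReport",
    "align_models",
    "inhibitor_union",
    "merge_rules",
    "merge_models",
    "rule_from_signed_edges",
]

Method = Literal["OR", "AND", "IW"]
_METHODS = ("OR", "AND", "IW")


@dataclass(frozen=True)
class MergeConfig:
    """How to merge: global method plus optional per-node overrides."""

    method: Method = "OR"
    per_node_overrides: Mapping[str, Method] = field(default_factory=dict)
    dual_as_inhibitor: bool = True
    name: str = "merged"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise MergeError(f"unknown merge method {self.method!r}; expected one of {_METHODS}")
        for sym, m in self.per_node_overrides.items():
            if m not in _METHODS:
                raise MergeError(f"unknown override method {m!r} for node {sym!r}")

    def method_for(self, symbol: str) -> Method:
        return self.per_node_overrides.get(symbol, self.method)


@dataclass
class MergeReport:
    """Bookkeeping for one merge: overlap structure and per-node choices."""

    overlapping_symbols: set[str] = field(default_factory=set)
    exclusive_symbols: dict[str, set[str]] = field(default_factory=dict)
    method_used: dict[str, str] = field(default_factory=dict)
    inhibitor_sets: dict[str, set[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overlapping_symbols": sorted(self.overlapping_symbols),
            "exclusive_symbols": {k: sorted(v) for k, v in self.exclusive_symbols.items()},
            "method_used": dict(sorted(self.method_used.items())),
            "inhibitor_sets": {k: sorted(v) for k, v in sorted(self.inhibitor_sets.items())},
        }


def _rule_holders(symbol: str, models: Sequence[LogicalModel]) -> list[LogicalModel]:
    """Models in which ``symbol`` has a rule of its own (not a mere input)."""
    holders = []
    for m in models:
        if symbol in m and not m.node(symbol).is_input:
            holders.append(m)
    return holders


def align_models(models: Sequence[LogicalModel]) -> MergeReport:
    """Partition the union symbol set into overlapping and exclusive nodes."""
    report = MergeReport()
    all_symbols: list[str] = []
    for m in models:
        for s in m.symbols:
            if s not in all_symbols:
                all_symbols.append(s)
    for symbol in all_symbols:
        holders = _rule_holders(symbol, models)
        if len(holders) >= 2:
            report.overlapping_symbols.add(symbol)
        elif len(holders) == 1:
            report.exclusive_symbols.setdefault(holders[0].name, set()).add(symbol)
        else:  # input everywhere — exclusive to the first model that carries it
            owner = next(m for m in models if symbol in m)
            report.exclusive_symbols.setdefault(owner.name, set()).add(symbol)
    return report


def inhibitor_union(
    symbol: str,
    models: Sequence[LogicalModel],
    dual_as_inhibitor: bool = True,
    sign_overrides: Mapping[tuple[str, str], InfluenceSign] | None = None,
    cap: int = 16,
) -> set[str]:
    """Union over models of the regulators with inhibitory influence on
    ``symbol``'s rule. ``sign_overrides`` maps (target, regulator) to a
    curated sign that replaces the functional classification."""
    holders = _rule_holders(symbol, models)
    if not holders:
        raise MergeError(f"symbol {symbol!r} has no rule in any model")
    inhibitory = {InfluenceSign.INHIBITOR}
    if dual_as_inhibitor:
        inhibitory.add(InfluenceSign.DUAL)
    out: set[str] = set()
    for m in holders:
        rule = m.rule(symbol)
        for reg in support(rule):
            if sign_overrides and (symbol, reg) in sign_overrides:
                sign = sign_overrides[(symbol, reg)]
            else:
                sign = classify_influence(rule, reg, cap=cap)
            if sign in inhibitory:
                out.add(reg)
    return out


def merge_rules(
    symbol: str,
    rules: Sequence[BoolExpr],
    method: Method,
    inhibitors: Iterable[str] = (),
) -> BoolExpr:
    """Combine source rules for one node under the chosen semantics."""
    if not rules:
        raise MergeError(f"no rules to merge for {symbol!r}")
    if method == "OR":
        return Or(*rules)
    if method == "AND":
        return And(*rules)
    if method == "IW":
        body = Or(*rules)
        guards = [Not(Var(i)) for i in sorted(set(inhibitors))]
        if not guards:
            return body
        return And(*guards, body)
    raise MergeError(f"unknown merge method {method!r}")


def merge_models(
    models: Sequence[LogicalModel],
    config: MergeConfig | None = None,
    sign_overrides: Mapping[tuple[str, str], InfluenceSign] | None = None,
    sign_cap: int = 16,
) -> tuple[LogicalModel, MergeReport]:
    """Merge two or more standardized models into one.

    Overlapping nodes get the combined rule; exclusive nodes are copied
    verbatim. Node order: first-appearance order across the input models.
    Annotations record the contributing source models per node.
    """
    if config is None:
        config = MergeConfig()
    if len(models) < 2:
        raise MergeError(f"need at least 2 models to merge, got {len(models)}")
    union: set[str] = set()
    for m in models:
        union |= set(m.symbols)
    for sym in config.per_node_overrides:
        if sym not in union:
            raise MergeError(f"per-node override for unknown symbol {sym!r}")

    report = align_models(models)
    order: list[str] = []
    for m in models:
        for s in m.symbols:
            if s not in order:
                order.append(s)

    nodes: list[NodeSpec] = []
    for symbol in order:
        holders = _rule_holders(symbol, models)
        sources = ",".join(m.name for m in models if symbol in m)
        if symbol in report.overlapping_symbols:
            method = config.method_for(symbol)
            try:
                inhibitors = (
                    inhibitor_union(
                        symbol, models,
                        dual_as_inhibitor=config.dual_as_inhibitor,
                        sign_overrides=sign_overrides,
                        cap=sign_cap,
                    )
                    if method == "IW"
                    else set()
                )
            except CapExceededError:
                raise
            rule = merge_rules(symbol, [m.rule(symbol) for m in holders], method, inhibitors)
            report.method_used[symbol] = method
            if method == "IW":
                report.inhibitor_sets[symbol] = inhibitors
            nodes.append(NodeSpec(symbol=symbol, rule=rule,
                                  annotations={"sources": sources, "merge_method": method}))
        elif holders:
            node = holders[0].node(symbol)
            report.method_used[symbol] = "verbatim"
            nodes.append(NodeSpec(symbol=symbol, rule=node.rule,
                                  annotations={**node.annotations, "sources": sources},
                                  is_input=node.is_input))
        else:  # external input in every model it appears in
            report.method_used[symbol] = "input"
            nodes.append(NodeSpec(symbol=symbol, rule=Var(symbol),
                                  annotations={"sources": sources}, is_input=True))

    merged = LogicalModel(config.name, nodes,
                          metadata={"sources": ",".join(m.name for m in models),
                                    "merge_method": config.method})
    return merged, report


def rule_from_signed_edges(
    activators: Iterable[str], inhibitors: Iterable[str]
) -> BoolExpr:
    """Translate an unsigned-logic interaction graph into a rule under the
    Inhibitor-Wins reading: OR of activators, AND-ed with NOT of each
    inhibitor. Useful when a source provides only a signed edge list."""
    acts = sorted(set(activators))
    inhs = sorted(set(inhibitors))
    if not acts and not inhs:
        raise MergeError("node needs at least one signed regulator")
    guards = [Not(Var(i)) for i in inhs]
    if acts:
        body = Or(*[Var(a) for a in acts])
        return And(*guards, body) if guards else body
    # purely inhibitory input: ON unless some inhibitor is active
    return And(*guards)
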