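"""In-memory representation of a Boolean regulatory-network model."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ModelFormatError
from .expr import BoolExpr, Var, support

__all__ = ["NodeSpec", "LogicalModel", "Finding", "validate_model", "resolve_inputs"]


@dataclass(frozen=True)
class NodeSpec:
    """One node: a standardized gene symbol plus its update rule.

    ``annotations`` holds provenance metadata (HGNC ID, source model,
    archived pre-perturbation rule, ...). ``is_input`` marks external inputs
    — regulators that had no rule in the source model and were given their
    own identity as rule so the state space stays well defined.
    """

    symbol: str
    rule: BoolExpr
    node_id: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)
    is_input: bool = False

    def __post_init__(self) -> None:
        if self.node_id is None:
            object.__setattr__(self, "node_id", self.symbol)


@dataclass
class LogicalModel:
    """A named, ordered collection of nodes with Boolean update rules."""

    name: str
    nodes: list[NodeSpec]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for node in self.nodes:
            if node.symbol in seen:
                raise ModelFormatError(
                    f"duplicate node symbol {node.symbol!r} in model {self.name!r}"
                )
            seen.add(node.symbol)

    @property
    def symbols(self) -> list[str]:
        return [n.symbol for n in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, symbol: str) -> bool:
        return any(n.symbol == symbol for n in self.nodes)

    def node(self, symbol: str) -> NodeSpec:
        for n in self.nodes:
            if n.symbol == symbol:
                return n
        raise KeyError(symbol)

    def rule(self, symbol: str) -> BoolExpr:
        return self.node(symbol).rule

    def regulators(self, symbol: str) -> frozenset[str]:
        return support(self.rule(symbol))

    def replace_rule(self, symbol: str, rule: BoolExpr, **annotations: str) -> "LogicalModel":
        """Copy of the model with one node's rule swapped out."""
        nodes = []
        for n in self.nodes:
            if n.symbol == symbol:
                n = replace(n, rule=rule, annotations={**n.annotations, **annotations})
            nodes.append(n)
        return LogicalModel(self.name, nodes, dict(self.metadata))


@dataclass(frozen=True)
class Finding:
    """One informational validation finding (never an exception)."""

    code: str
    symbol: str
    message: str


def validate_model(model: LogicalModel) -> list[Finding]:
    """Static checks: undefined regulators, unused nodes, constant rules,
    self-loops. Findings are informational; none of them is fatal."""
    findings: list[Finding] = []
    defined = set(model.symbols)
    used: set[str] = set()
    for node in model.nodes:
        regs = support(node.rule)
        used |= regs
        for reg in sorted(regs - defined):
            findings.append(
                Finding("UNDEFINED_REGULATOR", node.symbol,
                        f"rule of {node.symbol!r} references undefined regulator {reg!r}")
            )
        if node.rule.kind == "CONST":
            findings.append(
                Finding("CONSTANT_RULE", node.symbol,
                        f"rule of {node.symbol!r} is the constant {node.rule.value}")
            )
        if node.symbol in regs:
            findings.append(
                Finding("SELF_LOOP", node.symbol,
                        f"{node.symbol!r} regulates itself")
            )
    for symbol in sorted(defined - used):
        findings.append(
            Finding("UNUSED_NODE", symbol,
                    f"{symbol!r} does not regulate any node")
        )
    return findings


def resolve_inputs(model: LogicalModel) -> LogicalModel:
    """Give every undefined regulator an identity rule, flagged as input."""
    defined = set(model.symbols)
    referenced: set[str] = set()
    for node in model.nodes:
        referenced |= support(node.rule)
    extra = [
        NodeSpec(symbol=s, rule=Var(s), is_input=True)
        for s in sorted(referenced - defined)
    ]
    if not extra:
        return model
    return LogicalModel(model.name, list(model.nodes) + extra, dict(model.metadata))
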