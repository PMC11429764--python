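"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized truth-table
machinery: they evaluate expressions recursively over explicitly enumerated
assignments, so agreement between implementation and oracle is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from boolmerge import LogicalModel, NodeSpec
from boolmerge.expr import And, BoolExpr, Const, Not, Or, Var


# --- independent oracles ------------------------------------------------------

def brute_eval(expr: BoolExpr, env: dict[str, int]) -> int:
    """Plain recursive evaluation (no numpy, no package evaluate)."""
    if expr.kind == "CONST":
        return expr.value
    if expr.kind == "VAR":
        return env[expr.name]
    if expr.kind == "NOT":
        return 1 - brute_eval(expr.children[0], env)
    vals = [brute_eval(c, env) for c in expr.children]
    return min(vals) if expr.kind == "AND" else max(vals)


def brute_support(expr: BoolExpr) -> set[str]:
    if expr.kind == "VAR":
        return {expr.name}
    out: set[str] = set()
    for c in expr.children:
        out |= brute_support(c)
    return out


def all_assignments(variables: list[str]):
    for bits in itertools.product((0, 1), repeat=len(variables)):
        yield dict(zip(variables, bits))


def brute_sign(expr: BoolExpr, var: str) -> str:
    """Influence classification by full truth-table tabulation."""
    others = sorted(brute_support(expr) - {var})
    raises = lowers = False
    for env in all_assignments(others):
        lo = brute_eval(expr, {**env, var: 0})
        hi = brute_eval(expr, {**env, var: 1})
        if hi > lo:
            raises = True
        if hi < lo:
            lowers = True
    if raises and lowers:
        return "dual"
    if raises:
        return "activator"
    if lowers:
        return "inhibitor"
    return "none"


def brute_fixed_points(model: LogicalModel) -> list[tuple[int, ...]]:
    """Exhaustive enumeration of states with f(x) = x."""
    out = []
    symbols = model.symbols
    for bits in itertools.product((0, 1), repeat=len(symbols)):
        env = dict(zip(symbols, bits))
        if all(brute_eval(n.rule, env) == env[n.symbol] for n in model.nodes):
            out.append(bits)
    return out


def tarjan_terminal_sccs(nodes: list, edges: dict) -> list[frozenset]:
    """Iterative Tarjan SCC; returns the terminal (no outgoing edge) SCCs."""
    index: dict = {}
    low: dict = {}
    on_stack: set = set()
    stack: list = []
    sccs: list[frozenset] = []
    counter = [0]

    for root in nodes:
        if root in index:
            continue
        work = [(root, iter(edges.get(root, ())))]
        index[root] = low[root] = counter[0]
        counter[0] += 1
        stack.append(root)
        on_stack.add(root)
        while work:
            v, it = work[-1]
            advanced = False
            for w in it:
                if w not in index:
                    index[w] = low[w] = counter[0]
                    counter[0] += 1
                    stack.append(w)
                    on_stack.add(w)
                    work.append((w, iter(edges.get(w, ()))))
                    advanced = True
                    break
                if w in on_stack:
                    low[v] = min(low[v], index[w])
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                low[parent] = min(low[parent], low[v])
            if low[v] == index[v]:
                scc = set()
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    scc.add(w)
                    if w == v:
                        break
                sccs.append(frozenset(scc))

    terminal = []
    for scc in sccs:
        if all(w in scc for v in scc for w in edges.get(v, ())):
            terminal.append(scc)
    return terminal


# --- random generators for property tests ------------------------------------

def random_expr(rng: np.random.Generator, variables: list[str], depth: int = 4) -> BoolExpr:
    """Random expression tree over the given variables (may use a subset)."""
    if depth == 0 or rng.random() < 0.3:
        if rng.random() < 0.05:
            return Const(int(rng.integers(0, 2)))
        v = Var(str(rng.choice(variables)))
        return Not(v) if rng.random() < 0.4 else v
    op = rng.choice(["and", "or", "not"])
    if op == "not":
        return Not(random_expr(rng, variables, depth - 1))
    arity = int(rng.integers(2, 4))
    children = tuple(random_expr(rng, variables, depth - 1) for _ in range(arity))
    return And(*children) if op == "and" else Or(*children)


def random_closed_model(rng: np.random.Generator, n: int, k: int = 3,
                        name: str = "rand") -> LogicalModel:
    """Random model whose every regulator is a model node (closed support)."""
    symbols = [f"N{i}" for i in range(n)]
    nodes = []
    for sym in symbols:
        n_regs = int(rng.integers(1, min(k, n) + 1))
        regs = [str(s) for s in rng.choice(symbols, size=n_regs, replace=False)]
        nodes.append(NodeSpec(symbol=sym, rule=random_expr(rng, regs, depth=3)))
    return LogicalModel(name, nodes)


@pytest.fixture
def toy_negation_loop() -> LogicalModel:
    """A = !B, B = A: a 4-state synchronous limit cycle, two async fixed
    points do not exist (no fixed point at all)."""
    from boolmerge import parse_rule

    return LogicalModel("toy", [
        NodeSpec("A", parse_rule("!B")),
        NodeSpec("B", parse_rule("A")),
    ])


@pytest.fixture
def toy_mutual_activation() -> LogicalModel:
    """A = B, B = A: fixed points (0,0) and (1,1)."""
    from boolmerge import parse_rule

    return LogicalModel("mut", [
        NodeSpec("A", parse_rule("B")),
        NodeSpec("B", parse_rule("A")),
    ])
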