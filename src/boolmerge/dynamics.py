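"""State-space dynamics: synchronous/asynchronous updating, fixed points,
attractors, basins, and mutation clamping.

States are tuples of bits in the model's node order; the integer encoding
uses bit ``i`` for node ``i`` (first node = least-significant bit), so
heatmaps and serialized attractors are reproducible.

Exhaustive analysis is capped (default 22 nodes for attractors, 40 for the
constraint-propagating fixed-point search); beyond the attractor cap a
seeded sampling mode (synchronous only) can be enabled explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CapExceededError, MissingVariableError
from .expr import BoolExpr, Const, support, truth_table
from .model import LogicalModel

__all__ = [
    "State",
    "Attractor",
    "MutationProfile",
    "sync_step",
    "async_successors",
    "find_fixed_points",
    "find_attractors",
    "apply_perturbation",
    "attractors_to_json",
    "attractors_to_frame",
]

State = tuple[int, ...]
Scheme = Literal["SYNC", "ASYNC"]

EXHAUSTIVE_CAP = 22
FIXED_POINT_CAP = 40


@dataclass(frozen=True)
class Attractor:
    """A fixed point (one state) or cyclic attractor (>1 recurrent states).

    Under synchronous updating a cyclic attractor is the limit cycle of the
    deterministic map; under asynchronous updating it is a terminal strongly
    connected component of the state transition graph. ``basin_fraction`` is
    the share of all states whose trajectories end here (exact in exhaustive
    mode, an estimate in sampling mode).
    """

    kind: Literal["FIXED_POINT", "CYCLIC"]
    states: tuple[State, ...]
    basin_fraction: float | None = None
    label: str = ""
    approximate: bool = False

    def __post_init__(self) -> None:
        if self.kind == "FIXED_POINT" and len(self.states) != 1:
            raise ValueError("a fixed point has exactly one state")
        if self.kind == "CYCLIC" and len(self.states) < 2:
            raise ValueError("a cyclic attractor has at least two states")
        if len(set(self.states)) != len(self.states):
            raise ValueError("attractor states must be distinct")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class MutationProfile:
    """Per-gene clamps: gain-of-function -> 1, loss-of-function -> 0."""

    clamps: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, mapping: Mapping[str, int]) -> "MutationProfile":
        return cls(tuple(sorted((s, int(b)) for s, b in mapping.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.clamps)

    def __len__(self) -> int:
        return len(self.clamps)


def _state_map(model: LogicalModel, state: Sequence[int]) -> dict[str, int]:
    if len(state) != len(model):
        raise ValueError(
            f"state length {len(state)} does not match model size {len(model)}"
        )
    return {n.symbol: int(b) for n, b in zip(model.nodes, state)}


def sync_step(model: LogicalModel, state: Sequence[int]) -> State:
    """All nodes updated simultaneously: x'_i = f_i(x)."""
    from .expr import evaluate

    env = _state_map(model, state)
    return tuple(evaluate(n.rule, env) for n in model.nodes)


def async_successors(model: LogicalModel, state: Sequence[int]) -> set[State]:
    """One successor per node whose update changes its value; empty iff the
    state is a fixed point (general fully asynchronous scheme)."""
    from .expr import evaluate

    env = _state_map(model, state)
    out: set[State] = set()
    state = tuple(int(b) for b in state)
    for i, node in enumerate(model.nodes):
        new = evaluate(node.rule, env)
        if new != state[i]:
            out.add(state[:i] + (new,) + state[i + 1 :])
    return out


# --- fixed points ------------------------------------------------------------

def _simplify(expr: BoolExpr, env: Mapping[str, int]) -> BoolExpr:
    """Partial evaluation under a partial assignment."""
    if expr.kind == "CONST":
        return expr
    if expr.kind == "VAR":
        if expr.name in env:
            return Const(env[expr.name])  # type: ignore[index]
        return expr
    if expr.kind == "NOT":
        child = _simplify(expr.children[0], env)
        if child.kind == "CONST":
            return Const(1 - child.value)  # type: ignore[operator]
        return BoolExpr("NOT", children=(child,))
    keep: list[BoolExpr] = []
    absorbing = 0 if expr.kind == "AND" else 1
    for c in expr.children:
        s = _simplify(c, env)
        if s.kind == "CONST":
            if s.value == absorbing:
                return Const(absorbing)
            continue  # identity element: drop
        keep.append(s)
    if not keep:
        return Const(1 - absorbing)
    if len(keep) == 1:
        return keep[0]
    return BoolExpr(expr.kind, children=tuple(keep))


def find_fixed_points(model: LogicalModel, cap: int = FIXED_POINT_CAP) -> list[State]:
    """All states with f(x) = x, by branch-and-prune constraint propagation.

    Pick an undetermined node, try both values, propagate: whenever a node's
    rule simplifies to a constant, the fixed-point condition forces that
    node's value; contradictions prune the branch. Scheme-independent.
    Result sorted by integer encoding (bit i = node i).
    """
    n = len(model)
    if n > cap:
        raise CapExceededError(f"model has {n} nodes; fixed-point cap is {cap}")
    symbols = model.symbols
    order = {s: i for i, s in enumerate(symbols)}
    results: list[State] = []

    def propagate(env: dict[str, int], rules: dict[str, BoolExpr]) -> bool:
        """Returns False on contradiction; mutates env/rules in place."""
        changed = True
        while changed:
            changed = False
            for sym in symbols:
                simplified = _simplify(rules[sym], env)
                rules[sym] = simplified
                if simplified.kind == "CONST":
                    forced = simplified.value
                    if sym in env:
                        if env[sym] != forced:
                            return False
                    else:
                        env[sym] = forced  # type: ignore[assignment]
                        changed = True
                elif sym in env:
                    continue
        return True

    def branch(env: dict[str, int], rules: dict[str, BoolExpr]) -> None:
        if not propagate(env, rules):
            return
        undecided = [s for s in symbols if s not in env]
        if not undecided:
            state = tuple(env[s] for s in symbols)
            if sync_step(model, state) == state:  # guard against non-forced leftovers
                results.append(state)
            return
        pivot = undecided[0]
        for value in (0, 1):
            env2 = dict(env)
            env2[pivot] = value
            branch(env2, dict(rules))

    branch({}, {node.symbol: node.rule for node in model.nodes})
    unique = sorted(set(results), key=lambda s: _encode(s))
    return unique


def _encode(state: Sequence[int]) -> int:
    code = 0
    for i, b in enumerate(state):
        code |= int(b) << i
    return code


def _decode(code: int, n: int) -> State:
    return tuple((code >> i) & 1 for i in range(n))


def _successor_table(model: LogicalModel) -> np.ndarray:
    """Vector of synchronous successors for every state code."""
    symbols = model.symbols
    n = len(symbols)
    succ = np.zeros(1 << n, dtype=np.int64)
    for i, node in enumerate(model.nodes):
        succ |= truth_table(node.rule, symbols).astype(np.int64) << i
    return succ


def _default_namer(model: LogicalModel) -> Callable[[int], str]:
    initial = (model.name[:1] or "M").upper()
    return lambda idx: f"{initial}{idx + 1}"


def find_attractors(
    model: LogicalModel,
    scheme: Scheme = "SYNC",
    cap: int = EXHAUSTIVE_CAP,
    sampling: bool = False,
    n_samples: int = 1000,
    max_steps: int = 10_000,
    seed: int | None = None,
    namer: Callable[[int], str] | None = None,
) -> list[Attractor]:
    """Attractors of the network.

    Exhaustive mode (node count <= cap): SYNC iterates the deterministic map
    from every state and collects the unique limit cycles with exact basin
    fractions (which partition the state space); ASYNC builds the full
    nondeterministic transition graph and returns its terminal strongly
    connected components, reporting as basin the fraction of states from
    which the attractor is reachable (these may overlap and need not sum to
    1). Sampling mode (SYNC only, opt-in, mandatory seed) estimates from
    random trajectories and flags results approximate.

    Ordering: descending basin fraction, then smallest state code; labels
    come from ``namer`` (default: model initial + 1-based index).
    """
    n = len(model)
    for node in model.nodes:
        missing = support(node.rule) - set(model.symbols)
        if missing:
            raise MissingVariableError(sorted(missing)[0])
    if n > cap:
        if not (sampling and scheme == "SYNC"):
            raise CapExceededError(
                f"model has {n} nodes; exhaustive cap is {cap} "
                "(enable sampling=True with a seed for SYNC estimation)"
            )
    if sampling and scheme == "SYNC":
        if seed is None:
            raise ValueError("sampling mode requires a seed")
        return _sample_sync_attractors(model, n_samples, max_steps, seed, namer)
    if scheme == "SYNC":
        return _exact_sync_attractors(model, namer)
    if scheme == "ASYNC":
        return _exact_async_attractors(model, namer)
    raise ValueError(f"unknown update scheme {scheme!r}")


def _finalize(
    model: LogicalModel,
    raw: list[tuple[tuple[State, ...], float, bool]],
    namer: Callable[[int], str] | None,
) -> list[Attractor]:
    name = namer or _default_namer(model)
    raw.sort(key=lambda item: (-(item[1] if item[1] is not None else 0.0),
                               min(_encode(s) for s in item[0])))
    out = []
    for idx, (states, basin, approx) in enumerate(raw):
        kind = "FIXED_POINT" if len(states) == 1 else "CYCLIC"
        out.append(Attractor(kind=kind, states=states, basin_fraction=basin,
                             label=name(idx), approximate=approx))
    return out


def _canonical_cycle(cycle: list[State]) -> tuple[State, ...]:
    """Rotate so the smallest-encoded state comes first (stable identity)."""
    codes = [_encode(s) for s in cycle]
    start = codes.index(min(codes))
    return tuple(cycle[start:] + cycle[:start])


def _exact_sync_attractors(
    model: LogicalModel, namer: Callable[[int], str] | None
) -> list[Attractor]:
    n = len(model)
    succ = _successor_table(model)
    size = 1 << n
    color = np.full(size, -1, dtype=np.int64)  # attractor id per state
    attractor_states: list[tuple[State, ...]] = []
    basin_counts: list[int] = []

    for start in range(size):
        if color[start] >= 0:
            continue
        path: list[int] = []
        on_path: dict[int, int] = {}
        s = start
        while color[s] < 0 and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if color[s] >= 0:
            aid = int(color[s])
        else:  # new cycle discovered on this path
            cycle_start = on_path[s]
            cycle = [_decode(c, n) for c in path[cycle_start:]]
            aid = len(attractor_states)
            attractor_states.append(_canonical_cycle(cycle))
            basin_counts.append(0)
        for c in path:
            color[c] = aid
        basin_counts[aid] += len(path)

    raw = [
        (states, basin_counts[aid] / size, False)
        for aid, states in enumerate(attractor_states)
    ]
    return _finalize(model, raw, namer)


def _exact_async_attractors(
    model: LogicalModel, namer: Callable[[int], str] | None
) -> list[Attractor]:
    n = len(model)
    size = 1 << n
    graph = nx.DiGraph()
    graph.add_nodes_from(range(size))
    for code in range(size):
        state = _decode(code, n)
        for succ_state in async_successors(model, state):
            graph.add_edge(code, _encode(succ_state))

    condensation = nx.condensation(graph)
    terminal = [c for c in condensation.nodes if condensation.out_degree(c) == 0]
    # basin = fraction of states from which the terminal SCC is reachable
    reach = {c: 0 for c in terminal}
    anc = {c: nx.ancestors(condensation, c) | {c} for c in terminal}
    mapping = condensation.nodes
    for c in terminal:
        members = 0
        for scc in anc[c]:
            members += len(mapping[scc]["members"])
        reach[c] = members
    raw = []
    for c in terminal:
        codes = sorted(mapping[c]["members"])
        states = tuple(_decode(code, n) for code in codes)
        raw.append((states, reach[c] / size, False))
    return _finalize(model, raw, namer)


def _sample_sync_attractors(
    model: LogicalModel,
    n_samples: int,
    max_steps: int,
    seed: int,
    namer: Callable[[int], str] | None,
) -> list[Attractor]:
    from .expr import evaluate

    n = len(model)
    rng = np.random.default_rng(seed)
    found: dict[tuple[State, ...], int] = {}
    for _ in range(n_samples):
        state = tuple(int(b) for b in rng.integers(0, 2, size=n))
        seen: dict[State, int] = {}
        trajectory: list[State] = []
        for _ in range(max_steps):
            if state in seen:
                cycle = trajectory[seen[state]:]
                key = _canonical_cycle(cycle)
                found[key] = found.get(key, 0) + 1
                break
            seen[state] = len(trajectory)
            trajectory.append(state)
            state = sync_step(model, state)
    total = sum(found.values())
    raw = [(states, count / total, True) for states, count in found.items()]
    return _finalize(model, raw, namer)


def apply_perturbation(model: LogicalModel, profile: MutationProfile) -> LogicalModel:
    """Clamp mutated nodes: each clamped rule becomes the constant clamp
    value; the original rule is archived in the node's annotations."""
    from .expr import render

    out = model
    for symbol, clamp in profile.clamps:
        if symbol not in model:
            raise KeyError(f"mutation profile clamps unknown symbol {symbol!r}")
        original = out.rule(symbol)
        out = out.replace_rule(symbol, Const(clamp), original_rule=render(original))
    if profile.clamps:
        out.metadata["perturbation"] = ";".join(f"{s}={b}" for s, b in profile.clamps)
    return out


# --- serialization -----------------------------------------------------------

def attractors_to_json(model: LogicalModel, attractors: Sequence[Attractor]) -> str:
    """JSON document: symbol order plus per-attractor bitstrings and basins."""
    doc = {
        "model": model.name,
        "symbols": model.symbols,
        "attractors": [
            {
                "label": a.label,
                "kind": a.kind,
                "states": ["".join(str(b) for b in s) for s in a.states],
                "basin_fraction": a.basin_fraction,
                "approximate": a.approximate,
            }
            for a in attractors
        ],
    }
    return json.dumps(doc, indent=2)


def attractors_to_frame(model: LogicalModel, attractors: Sequence[Attractor]) -> pd.DataFrame:
    """Tidy attractor-by-gene table (one row per attractor state)."""
    rows = []
    for a in attractors:
        for j, state in enumerate(a.states):
            row: dict[str, object] = {"attractor": a.label, "kind": a.kind, "state_index": j}
            row.update({sym: b for sym, b in zip(model.symbols, state)})
            rows.append(row)
    return pd.DataFrame(rows)
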