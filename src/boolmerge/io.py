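"""Model I/O: BoolNet-style ``.bnet`` text, SBML-qual XML, and gene-symbol
standardization against an offline HGNC mapping table.

The SBML-qual dialect written here is SBML Level 3 Version 1 with the qual
v1 package: one Boolean qualitative species per node (maxLevel 1) and one
transition per node whose single function term (resultLevel 1) carries the
rule as MathML ``and``/``or``/``not`` over ``eq(species, 1)`` comparisons.
Multi-valued models (maxLevel > 1) are out of scope and rejected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from lxml import etree

from .errors import ModelFormatError, StandardizationError, UnsupportedModelError
from .expr import And, BoolExpr, Const, Not, Or, Var, classify_influence, parse_rule, render, support
from .expr import InfluenceSign
from .model import LogicalModel, NodeSpec, resolve_inputs

__all__ = [
    "read_bnet",
    "write_bnet",
    "read_sbml_qual",
    "write_sbml_qual",
    "read_model",
    "write_model",
    "IdentifierMapping",
    "read_mapping",
    "StandardizationReport",
    "standardize_symbols",
]

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATH_NS = "http://www.w3.org/1998/Math/MathML"
_NSMAP = {None: _SBML_NS, "qual": _QUAL_NS}


def _q(tag: str) -> str:
    return f"{{{_QUAL_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{_MATH_NS}}}{tag}"


def _s(tag: str) -> str:
    return f"{{{_SBML_NS}}}{tag}"


# --- BoolNet-style text format ----------------------------------------------

def read_bnet(path: str | os.PathLike) -> LogicalModel:
    """Read a ``targets, factors`` rule list.

    Lines starting with ``#`` and blank lines are skipped; the header line is
    optional. Undefined regulators become identity-rule input nodes.
    """
    path = Path(path)
    nodes: list[NodeSpec] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise ModelFormatError(f"{path.name}:{lineno}: expected 'target, rule'")
        target, rule_text = line.split(",", 1)
        target = target.strip()
        if not target:
            raise ModelFormatError(f"{path.name}:{lineno}: empty target")
        if target in seen:
            raise ModelFormatError(f"{path.name}:{lineno}: duplicate target {target!r}")
        seen.add(target)
        try:
            rule = parse_rule(rule_text)
        except ValueError as exc:
            raise ModelFormatError(f"{path.name}:{lineno}: {exc}") from exc
        nodes.append(NodeSpec(symbol=target, rule=rule))
    if not nodes:
        raise ModelFormatError(f"{path.name}: no rules found")
    return resolve_inputs(LogicalModel(path.stem, nodes))


def write_bnet(model: LogicalModel, path: str | os.PathLike) -> None:
    lines = ["targets, factors"]
    for node in model.nodes:
        lines.append(f"{node.symbol}, {render(node.rule)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --- SBML-qual ---------------------------------------------------------------

def _rule_to_mathml(expr: BoolExpr) -> etree._Element:
    if expr.kind == "CONST":
        return etree.Element(_m("true" if expr.value else "false"))
    if expr.kind == "VAR":
        apply = etree.Element(_m("apply"))
        etree.SubElement(apply, _m("eq"))
        ci = etree.SubElement(apply, _m("ci"))
        ci.text = f" {expr.name} "
        cn = etree.SubElement(apply, _m("cn"))
        cn.set("type", "integer")
        cn.text = " 1 "
        return apply
    apply = etree.Element(_m("apply"))
    etree.SubElement(apply, _m(expr.kind.lower()))
    for child in expr.children:
        apply.append(_rule_to_mathml(child))
    return apply


def _mathml_to_rule(element: etree._Element, path: str) -> BoolExpr:
    tag = etree.QName(element).localname
    if tag == "true":
        return Const(1)
    if tag == "false":
        return Const(0)
    if tag == "ci":
        return Var((element.text or "").strip())
    if tag != "apply":
        raise ModelFormatError(f"{path}: unsupported MathML element <{tag}>")
    children = [c for c in element if isinstance(c.tag, str)]
    if not children:
        raise ModelFormatError(f"{path}: empty <apply>")
    op = etree.QName(children[0]).localname
    args = children[1:]
    if op in ("and", "or"):
        parsed = [_mathml_to_rule(a, path) for a in args]
        if len(parsed) < 1:
            raise ModelFormatError(f"{path}: <{op}> needs arguments")
        if len(parsed) == 1:
            return parsed[0]
        return And(*parsed) if op == "and" else Or(*parsed)
    if op == "not":
        if len(args) != 1:
            raise ModelFormatError(f"{path}: <not> takes one argument")
        return Not(_mathml_to_rule(args[0], path))
    if op in ("eq", "geq"):
        if len(args) != 2:
            raise ModelFormatError(f"{path}: <{op}> takes two arguments")
        ci, cn = args
        if etree.QName(ci).localname != "ci" or etree.QName(cn).localname != "cn":
            raise ModelFormatError(f"{path}: expected <ci> compared to <cn>")
        name = (ci.text or "").strip()
        level = int(float((cn.text or "").strip()))
        if level not in (0, 1):
            raise UnsupportedModelError(f"{path}: comparison to level {level} (not Boolean)")
        if op == "geq" and level == 0:
            return Const(1)
        var = Var(name)
        return var if level == 1 else Not(var)
    raise ModelFormatError(f"{path}: unsupported MathML operator <{op}>")


def read_sbml_qual(path: str | os.PathLike) -> LogicalModel:
    """Read an SBML Level 3 qual model with Boolean (maxLevel 1) species."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ModelFormatError(f"{path.name}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise ModelFormatError(f"{path.name}: root element is not <sbml>")
    model_el = root.find(_s("model"))
    if model_el is None:
        raise ModelFormatError(f"{path.name}: missing <model>")
    name = model_el.get("id") or model_el.get("name") or path.stem

    species_order: list[str] = []
    for sp in model_el.iter(_q("qualitativeSpecies")):
        sid = sp.get(_q("id"))
        if sid is None:
            raise ModelFormatError(f"{path.name}: qualitativeSpecies without qual:id")
        max_level = sp.get(_q("maxLevel"))
        if max_level is not None and int(max_level) != 1:
            raise UnsupportedModelError(
                f"{path.name}: species {sid!r} has maxLevel {max_level}; "
                "only Boolean (maxLevel 1) models are supported"
            )
        species_order.append(sid)
    if not species_order:
        raise ModelFormatError(f"{path.name}: no qualitative species")

    rules: dict[str, BoolExpr] = {}
    for tr in model_el.iter(_q("transition")):
        outputs = [o.get(_q("qualitativeSpecies")) for o in tr.iter(_q("output"))]
        if len(outputs) != 1 or outputs[0] is None:
            raise ModelFormatError(f"{path.name}: each transition needs exactly one output")
        target = outputs[0]
        if target in rules:
            raise ModelFormatError(f"{path.name}: multiple transitions target {target!r}")
        default_level = 0
        terms: list[tuple[int, BoolExpr]] = []
        for dt in tr.iter(_q("defaultTerm")):
            default_level = int(dt.get(_q("resultLevel"), "0"))
        for ft in tr.iter(_q("functionTerm")):
            level = int(ft.get(_q("resultLevel"), "0"))
            math = ft.find(_m("math"))
            if math is None or not len(math):
                raise ModelFormatError(f"{path.name}: functionTerm without <math>")
            body = [c for c in math if isinstance(c.tag, str)]
            terms.append((level, _mathml_to_rule(body[0], path.name)))
        if default_level not in (0, 1):
            raise UnsupportedModelError(f"{path.name}: non-Boolean result level {default_level}")
        if not terms:
            raise ModelFormatError(f"{path.name}: transition for {target!r} has no function terms")
        ones = [e for lvl, e in terms if lvl == 1]
        zeros = [e for lvl, e in terms if lvl == 0]
        if default_level == 0:
            rule = Or(*ones) if ones else Const(0)
        else:
            # ON unless some explicit OFF condition fires
            off = Or(*zeros) if zeros else Const(0)
            rule = Not(off) if not ones else Or(Or(*ones), Not(off))
        rules[target] = rule

    nodes = []
    for sid in species_order:
        if sid in rules:
            nodes.append(NodeSpec(symbol=sid, rule=rules[sid]))
        else:
            nodes.append(NodeSpec(symbol=sid, rule=Var(sid), is_input=True))
    return resolve_inputs(LogicalModel(name, nodes))


def write_sbml_qual(model: LogicalModel, path: str | os.PathLike) -> None:
    root = etree.Element(_s("sbml"), nsmap=_NSMAP)
    root.set("level", "3")
    root.set("version", "1")
    root.set(_q("required"), "true")
    model_el = etree.SubElement(root, _s("model"))
    model_el.set("id", _sanitize_sid(model.name) or "model")

    comps = etree.SubElement(model_el, _s("listOfCompartments"))
    comp = etree.SubElement(comps, _s("compartment"))
    comp.set("id", "default")
    comp.set("constant", "true")

    species_list = etree.SubElement(model_el, _q("listOfQualitativeSpecies"))
    for node in model.nodes:
        sp = etree.SubElement(species_list, _q("qualitativeSpecies"))
        sp.set(_q("id"), node.symbol)
        sp.set(_q("name"), node.symbol)
        sp.set(_q("compartment"), "default")
        sp.set(_q("constant"), "false")
        sp.set(_q("maxLevel"), "1")

    transitions = etree.SubElement(model_el, _q("listOfTransitions"))
    for node in model.nodes:
        tr = etree.SubElement(transitions, _q("transition"))
        tr.set(_q("id"), f"tr_{node.symbol}")
        regulators = sorted(support(node.rule))
        if regulators:
            inputs = etree.SubElement(tr, _q("listOfInputs"))
            for reg in regulators:
                inp = etree.SubElement(inputs, _q("input"))
                inp.set(_q("id"), f"tr_{node.symbol}_in_{reg}")
                inp.set(_q("qualitativeSpecies"), reg)
                inp.set(_q("transitionEffect"), "none")
                sign = classify_influence(node.rule, reg)
                inp.set(_q("sign"), {
                    InfluenceSign.ACTIVATOR: "positive",
                    InfluenceSign.INHIBITOR: "negative",
                    InfluenceSign.DUAL: "dual",
                    InfluenceSign.NONE: "unknown",
                }[sign])
        outputs = etree.SubElement(tr, _q("listOfOutputs"))
        out = etree.SubElement(outputs, _q("output"))
        out.set(_q("id"), f"tr_{node.symbol}_out")
        out.set(_q("qualitativeSpecies"), node.symbol)
        out.set(_q("transitionEffect"), "assignmentLevel")
        terms = etree.SubElement(tr, _q("listOfFunctionTerms"))
        dt = etree.SubElement(terms, _q("defaultTerm"))
        dt.set(_q("resultLevel"), "0")
        ft = etree.SubElement(terms, _q("functionTerm"))
        ft.set(_q("resultLevel"), "1")
        math = etree.SubElement(ft, _m("math"))
        math.append(_rule_to_mathml(node.rule))

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _sanitize_sid(name: str) -> str:
    return "".join(c if c.isalnum() or c == "_" else "_" for c in name)


def read_model(path: str | os.PathLike) -> LogicalModel:
    """Dispatch on extension: ``.bnet``/``.txt`` -> text rules, else SBML-qual."""
    suffix = Path(path).suffix.lower()
    if suffix in (".bnet", ".txt"):
        return read_bnet(path)
    return read_sbml_qual(path)


def write_model(model: LogicalModel, path: str | os.PathLike) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in (".bnet", ".txt"):
        write_bnet(model, path)
    else:
        write_sbml_qual(model, path)


# --- identifier standardization ---------------------------------------------

@dataclass(frozen=True)
class IdentifierMapping:
    """Offline raw-name -> HGNC symbol/ID table (one row per raw name)."""

    symbol_for: dict[str, str]
    hgnc_id_for: dict[str, str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IdentifierMapping":
        required = {"raw_name", "hgnc_symbol"}
        if not required.issubset(frame.columns):
            raise ModelFormatError(
                f"mapping table needs columns {sorted(required)}, got {list(frame.columns)}"
            )
        if frame["raw_name"].duplicated().any():
            dups = frame.loc[frame["raw_name"].duplicated(), "raw_name"].tolist()
            raise ModelFormatError(f"duplicate raw_name rows in mapping table: {dups}")
        if frame["hgnc_symbol"].isna().any() or (frame["hgnc_symbol"].astype(str) == "").any():
            raise ModelFormatError("mapping table has empty hgnc_symbol entries")
        ids = frame["hgnc_id"] if "hgnc_id" in frame.columns else pd.Series("", index=frame.index)
        return cls(
            symbol_for=dict(zip(frame["raw_name"].astype(str), frame["hgnc_symbol"].astype(str))),
            hgnc_id_for=dict(zip(frame["raw_name"].astype(str), ids.fillna("").astype(str))),
        )


def read_mapping(path: str | os.PathLike) -> IdentifierMapping:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return IdentifierMapping.from_frame(frame)


@dataclass
class StandardizationReport:
    """Outcome of symbol standardization: what mapped, what did not."""

    mapped: list[tuple[str, str]] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)
    collisions: dict[str, list[str]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.collisions


def standardize_symbols(
    model: LogicalModel, mapping: IdentifierMapping
) -> tuple[LogicalModel, StandardizationReport]:
    """Rewrite node symbols and rule variables to HGNC symbols.

    Substitution is simultaneous (a single pass over the original names, so
    chains like A->B, B->C cannot cascade). Names absent from the table are
    kept verbatim and reported. Two distinct nodes mapping to one symbol is
    a collision — surfaced as StandardizationError for manual curation.
    """
    report = StandardizationReport()
    new_symbol: dict[str, str] = {}
    for sym in model.symbols:
        if sym in mapping.symbol_for:
            new_symbol[sym] = mapping.symbol_for[sym]
            report.mapped.append((sym, mapping.symbol_for[sym]))
        else:
            new_symbol[sym] = sym
            report.unmapped.append(sym)

    targets: dict[str, list[str]] = {}
    for raw, std in new_symbol.items():
        targets.setdefault(std, []).append(raw)
    report.collisions = {std: raws for std, raws in targets.items() if len(raws) > 1}
    if report.collisions:
        detail = "; ".join(
            f"{std!r} <- {sorted(raws)}" for std, raws in sorted(report.collisions.items())
        )
        raise StandardizationError(f"symbol collision(s) after standardization: {detail}")

    def rewrite(expr: BoolExpr) -> BoolExpr:
        if expr.kind == "VAR":
            name = expr.name
            return Var(mapping.symbol_for.get(name, name))  # type: ignore[arg-type]
        if expr.kind in ("CONST",):
            return expr
        return replace(expr, children=tuple(rewrite(c) for c in expr.children))

    nodes = []
    for node in model.nodes:
        annotations = dict(node.annotations)
        if node.symbol in mapping.symbol_for:
            hgnc_id = mapping.hgnc_id_for.get(node.symbol, "")
            if hgnc_id:
                annotations["hgnc_id"] = hgnc_id
            annotations.setdefault("raw_name", node.symbol)
        nodes.append(
            replace(node, symbol=new_symbol[node.symbol], rule=rewrite(node.rule),
                    annotations=annotations)
        )
    return LogicalModel(model.name, nodes, dict(model.metadata)), report
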