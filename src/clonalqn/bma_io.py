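"""Read and write QN models in a BMA-compatible JSON dialect.

The document layout mirrors publicly documented BioModelAnalyzer model
files: a ``Model`` block with ``Variables`` (``Id``/``Name``/``RangeFrom``/
``RangeTo``/``Formula``) and ``Relationships`` (``Id``/``FromVariable``/
``ToVariable``/``Type``), plus an optional ``Layout`` block that is ignored
semantically but preserved on round-trip.  App-specific per-variable fields
(pathway tag, druggability flag, constitutive constant) live in a
namespaced ``Extensions.clonalqn`` block so files stay loadable by tools
expecting plain BMA JSON.  An empty ``Formula`` string selects the default
target function.

The formula grammar matches the BMA target-function language::

    expr    := term (("+" | "-") term)*
    term    := factor (("*" | "/") factor)*
    factor  := "-" factor | primary
    primary := NUMBER | func "(" expr ("," expr)* ")" | var | "(" expr ")"
    func    := "avg" | "min" | "max" | "ceil" | "floor"     (case-insensitive)
    var     := "var" "(" NAME | "NAME" | ID ")"

Numbers may be decimal (targets are real-valued).
"""

from __future__ import annotations

import json
from typing import Mapping

from .qn_core import (
    Avg,
    Binary,
    Const,
    QNModel,
    QNModelError,
    RelationshipDef,
    Unary,
    Var,
    VariableDef,
)

__all__ = [
    "FormulaSyntaxError",
    "parse_formula",
    "formula_to_text",
    "parse_model",
    "serialize_model",
    "load_model",
    "save_model",
]


class FormulaSyntaxError(QNModelError):
    """Raised with the character position of the offending token."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# --------------------------------------------------------------------------
# Formula text <-> AST
# --------------------------------------------------------------------------

_FUNCTIONS = {"avg", "min", "max", "ceil", "floor", "var"}


def _tokenize(text: str):
    tokens = []  # (kind, value, position)
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "+-*/(),":
            tokens.append((c, c, i))
            i += 1
            continue
        if c == '"' or c == "'":
            j = text.find(c, i + 1)
            if j < 0:
                raise FormulaSyntaxError("unterminated string", i)
            tokens.append(("name", text[i + 1 : j], i))
            i = j + 1
            continue
        if c.isdigit() or c == ".":
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            try:
                value = float(text[i:j])
            except ValueError:
                raise FormulaSyntaxError(f"bad number {text[i:j]!r}", i) from None
            tokens.append(("number", value, i))
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(("word", text[i:j], i))
            i = j
            continue
        raise FormulaSyntaxError(f"unexpected character {c!r}", i)
    tokens.append(("end", None, n))
    return tokens


class _Parser:
    def __init__(self, text: str, scope=None):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0
        self.scope = scope

    def peek(self):
        return self.tokens[self.pos]

    def next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, kind):
        tok = self.next()
        if tok[0] != kind:
            raise FormulaSyntaxError(f"expected {kind!r}, found {tok[1]!r}", tok[2])
        return tok

    def parse(self):
        expr = self.expr()
        tok = self.peek()
        if tok[0] != "end":
            raise FormulaSyntaxError(f"unexpected trailing token {tok[1]!r}", tok[2])
        return expr

    def expr(self):
        node = self.term()
        while self.peek()[0] in ("+", "-"):
            op = self.next()[0]
            node = Binary(op, node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek()[0] in ("*", "/"):
            op = self.next()[0]
            node = Binary(op, node, self.factor())
        return node

    def factor(self):
        if self.peek()[0] == "-":
            self.next()
            return Unary("neg", self.factor())
        return self.primary()

    def primary(self):
        kind, value, pos = self.next()
        if kind == "number":
            return Const(value)
        if kind == "(":
            node = self.expr()
            self.expect(")")
            return node
        if kind == "word":
            name = value.lower()
            if name not in _FUNCTIONS:
                raise FormulaSyntaxError(f"unknown function {value!r}", pos)
            self.expect("(")
            if name == "var":
                return self._var_ref()
            args = [self.expr()]
            while self.peek()[0] == ",":
                self.next()
                args.append(self.expr())
            self.expect(")")
            if name == "avg":
                return Avg(tuple(args))
            if name in ("min", "max"):
                if len(args) < 2:
                    raise FormulaSyntaxError(f"{name} needs at least 2 arguments", pos)
                node = args[0]
                for a in args[1:]:
                    node = Binary(name, node, a)
                return node
            # ceil / floor
            if len(args) != 1:
                raise FormulaSyntaxError(f"{name} takes exactly 1 argument", pos)
            return Unary(name, args[0])
        raise FormulaSyntaxError(f"unexpected token {value!r}", pos)

    def _var_ref(self):
        kind, value, pos = self.next()
        if kind == "word" or kind == "name":
            ref = value
        elif kind == "number":
            if float(value) != int(value):
                raise FormulaSyntaxError("variable id must be an integer", pos)
            ref = int(value)
        else:
            raise FormulaSyntaxError(f"bad var() reference {value!r}", pos)
        self.expect(")")
        if self.scope is not None:
            if isinstance(ref, int):
                if ref not in self.scope.get("ids", ()):  # pragma: no cover - id path
                    raise FormulaSyntaxError(f"var({ref}) is not a known variable id", pos)
                ref = self.scope["ids"][ref]
            elif ref not in self.scope.get("names", ()):
                raise FormulaSyntaxError(f"var({ref!r}) is not in scope", pos)
        return Var(ref if isinstance(ref, str) else str(ref))


def parse_formula(text: str, scope=None):
    """Parse a target-function expression.

    ``scope`` may be a set of admissible variable names, or a mapping with
    ``names`` (set of names) and ``ids`` (id -> name) used to resolve
    ``var(3)``-style references.  ``None`` skips scope checking.
    """
    if scope is not None and not isinstance(scope, Mapping):
        scope = {"names": set(scope), "ids": {}}
    return _Parser(text, scope).parse()


def _num_to_text(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def formula_to_text(expr) -> str:
    """Deterministic printer; ``parse_formula`` inverts it structurally."""
    if isinstance(expr, Const):
        return _num_to_text(expr.value)
    if isinstance(expr, Var):
        return f"var({expr.name})"
    if isinstance(expr, Avg):
        return "avg(" + ",".join(formula_to_text(a) for a in expr.args) + ")"
    if isinstance(expr, Unary):
        if expr.op == "neg":
            return "-(" + formula_to_text(expr.arg) + ")"
        return f"{expr.op}(" + formula_to_text(expr.arg) + ")"
    if isinstance(expr, Binary):
        if expr.op in ("min", "max"):
            return f"{expr.op}({formula_to_text(expr.left)},{formula_to_text(expr.right)})"
        return f"({formula_to_text(expr.left)}{expr.op}{formula_to_text(expr.right)})"
    raise QNModelError(f"unknown formula node {expr!r}")


# --------------------------------------------------------------------------
# Model documents
# --------------------------------------------------------------------------

def _require(cond: bool, path: str, message: str):
    if not cond:
        raise QNModelError(f"{path}: {message}")


def parse_model(text_or_doc) -> QNModel:
    """Parse a model document (JSON text or an already-decoded dict).

    Errors carry the JSON path of the offending record; formula syntax
    errors additionally carry the character offset within the formula.
    """
    if isinstance(text_or_doc, (str, bytes)):
        doc = json.loads(text_or_doc)
    else:
        doc = text_or_doc
    _require(isinstance(doc, dict), "$", "document must be a JSON object")
    _require("Model" in doc, "$", "missing 'Model' block")
    mblock = doc["Model"]
    _require(isinstance(mblock, dict), "$.Model", "must be an object")
    raw_vars = mblock.get("Variables", [])
    raw_rels = mblock.get("Relationships", [])
    _require(isinstance(raw_vars, list), "$.Model.Variables", "must be a list")
    _require(isinstance(raw_rels, list), "$.Model.Relationships", "must be a list")

    ext = doc.get("Extensions", {}).get("clonalqn", {})
    ext_vars = ext.get("variables", {}) if isinstance(ext, dict) else {}

    names = set()
    ids: dict = {}
    records = []
    for k, rec in enumerate(raw_vars):
        path = f"$.Model.Variables[{k}]"
        _require(isinstance(rec, dict), path, "must be an object")
        for key in ("Id", "Name", "RangeFrom", "RangeTo"):
            _require(key in rec, path, f"missing {key!r}")
        _require(rec["Id"] not in ids, path, f"duplicate variable id {rec['Id']}")
        _require(rec["Name"] not in names, path, f"duplicate variable name {rec['Name']!r}")
        ids[rec["Id"]] = rec["Name"]
        names.add(rec["Name"])
        records.append((path, rec))

    scope = {"names": names, "ids": ids}
    variables = []
    for path, rec in records:
        formula_text = rec.get("Formula", "") or ""
        if formula_text.strip():
            try:
                formula = parse_formula(formula_text, scope)
            except FormulaSyntaxError as e:
                raise QNModelError(f"{path}.Formula: {e}") from e
        else:
            formula = None
        meta = ext_vars.get(str(rec["Id"]), {})
        variables.append(
            VariableDef(
                id=int(rec["Id"]),
                name=str(rec["Name"]),
                range_min=int(rec["RangeFrom"]),
                range_max=int(rec["RangeTo"]),
                formula=formula,
                constitutive=meta.get("constitutive"),
                pathway=meta.get("pathway", ""),
                druggable=bool(meta.get("druggable", False)),
            )
        )

    relationships = []
    for k, rec in enumerate(raw_rels):
        path = f"$.Model.Relationships[{k}]"
        _require(isinstance(rec, dict), path, "must be an object")
        for key in ("FromVariable", "ToVariable", "Type"):
            _require(key in rec, path, f"missing {key!r}")
        _require(
            rec["FromVariable"] in ids,
            path,
            f"dangling FromVariable id {rec['FromVariable']}",
        )
        _require(
            rec["ToVariable"] in ids,
            path,
            f"dangling ToVariable id {rec['ToVariable']}",
        )
        sign = str(rec["Type"]).lower()
        _require(sign in ("activator", "inhibitor"), path, f"bad Type {rec['Type']!r}")
        relationships.append(
            RelationshipDef(int(rec["FromVariable"]), int(rec["ToVariable"]), sign)
        )

    model = QNModel(variables, relationships, name=str(mblock.get("Name", "qn")))
    # preserve unknown blocks (Layout and anything else) for round-trip
    extras = {k: v for k, v in doc.items() if k not in ("Model", "Extensions")}
    model.document_extras = extras
    return model


def serialize_model(model: QNModel) -> dict:
    """Model -> document dict; ``parse_model`` inverts it semantically."""
    variables = []
    ext_vars = {}
    for v in model.variables:
        variables.append(
            {
                "Id": v.id,
                "Name": v.name,
                "RangeFrom": v.range_min,
                "RangeTo": v.range_max,
                "Formula": "" if v.formula is None else formula_to_text(v.formula),
            }
        )
        meta = {}
        if v.pathway:
            meta["pathway"] = v.pathway
        if v.druggable:
            meta["druggable"] = True
        if v.constitutive is not None:
            meta["constitutive"] = v.constitutive
        if meta:
            ext_vars[str(v.id)] = meta
    relationships = [
        {
            "Id": k + 1,
            "FromVariable": r.from_id,
            "ToVariable": r.to_id,
            "Type": r.sign.capitalize(),
        }
        for k, r in enumerate(model.relationships)
    ]
    doc = {
        "Model": {
            "Name": model.name,
            "Variables": variables,
            "Relationships": relationships,
        }
    }
    if ext_vars:
        doc["Extensions"] = {"clonalqn": {"variables": ext_vars}}
    for key, value in getattr(model, "document_extras", {}).items():
        doc[key] = value
    return doc


def serialize_model_text(model: QNModel) -> str:
    return json.dumps(serialize_model(model), indent=2, sort_keys=True) + "\n"


def load_model(path) -> QNModel:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read())


def save_model(model: QNModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_model_text(model))
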