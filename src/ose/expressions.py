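"""Typed expression trees for edit-check rules.

Rules attached to study items ("the systolic value must exceed 121") are
represented as trees of *relators* — logical and arithmetic operators — over
numbers, named constants and references to study elements.  The surface
syntax is an s-expression:

    (AND (>= item:SYSTOLIC_BLOOD_PRESURE 0) (< item:SYSTOLIC_BLOOD_PRESURE 300))

Leaves are numbers (``121``, ``3.5``), boolean literals (``true``/``false``),
constant references (``const:NAME``) and element references (``item:NAME``).
Parsing validates operator arity and operand types up front, so a well-typed
tree never raises a type error during evaluation.  Missing bindings are an
error by default — rules guard data entry, and silently treating absent data
as null would hide defects; ``partial=True`` returns ``None`` ("unknown")
instead, for screening use.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Optional

from .errors import ExpressionError
from .frames import OntologyModel

BOOLEAN = "boolean"
NUMERIC = "numeric"
ANY = "any"


@dataclass(frozen=True)
class Operator:
    name: str
    min_arity: int
    max_arity: Optional[int]  # None = variadic
    operand_type: str
    result_type: str


class OperatorTable:
    """Registry of relators; extensible with user-defined operators."""

    def __init__(self, operators=()):
        self._by_name: dict[str, Operator] = {}
        for op in operators:
            self.register(op)

    def register(self, op: Operator) -> None:
        if op.name in self._by_name:
            raise ExpressionError(f"operator {op.name!r} already registered")
        self._by_name[op.name] = op

    def get(self, name: str) -> Operator:
        try:
            return self._by_name[name]
        except KeyError:
            raise ExpressionError(f"unknown operator {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def names(self) -> list[str]:
        return sorted(self._by_name)


def default_operator_table() -> OperatorTable:
    return OperatorTable(
        [
            Operator("AND", 2, None, BOOLEAN, BOOLEAN),
            Operator("OR", 2, None, BOOLEAN, BOOLEAN),
            Operator("NOT", 1, 1, BOOLEAN, BOOLEAN),
            Operator(">", 2, 2, NUMERIC, BOOLEAN),
            Operator("<", 2, 2, NUMERIC, BOOLEAN),
            Operator(">=", 2, 2, NUMERIC, BOOLEAN),
            Operator("<=", 2, 2, NUMERIC, BOOLEAN),
            Operator("=", 2, 2, ANY, BOOLEAN),
            Operator("+", 2, None, NUMERIC, NUMERIC),
            Operator("*", 2, None, NUMERIC, NUMERIC),
            Operator("-", 2, 2, NUMERIC, NUMERIC),
            Operator("/", 2, 2, NUMERIC, NUMERIC),
        ]
    )


DEFAULT_OPERATORS = default_operator_table()


@dataclass
class ExpressionNode:
    """One node of an expression tree.

    ``node_kind`` is one of ``relator``, ``number``, ``boolean``,
    ``constant_ref``, ``element_ref``.  Relators carry ``operator`` and
    ``args``; numbers/booleans carry ``value``; references carry the surface
    ``name`` and, when resolved against a model, the target instance id in
    ``ref``.
    """

    node_kind: str
    operator: Optional[str] = None
    args: list["ExpressionNode"] = field(default_factory=list)
    value: Any = None
    name: Optional[str] = None
    ref: Optional[str] = None

    def __eq__(self, other):  # structural equality; the resolved id is derived
        if not isinstance(other, ExpressionNode):
            return NotImplemented
        return (
            self.node_kind == other.node_kind
            and self.operator == other.operator
            and self.value == other.value
            and self.name == other.name
            and self.args == other.args
        )


_NUMBER_RE = re.compile(r"[+-]?(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?\Z")
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    tokens = _TOKEN_RE.findall(text)
    stripped = re.sub(r"\s+", "", text)
    if "".join(tokens) != stripped:
        raise ExpressionError(f"cannot tokenize expression {text!r}")
    return tokens


def _atom(token: str) -> ExpressionNode:
    if _NUMBER_RE.match(token):
        value = float(token)
        if value.is_integer() and "." not in token and "e" not in token.lower():
            value = int(token)
        return ExpressionNode("number", value=value)
    if token == "true":
        return ExpressionNode("boolean", value=True)
    if token == "false":
        return ExpressionNode("boolean", value=False)
    if token.startswith("const:"):
        return ExpressionNode("constant_ref", name=token[len("const:"):])
    if token.startswith("item:"):
        return ExpressionNode("element_ref", name=token[len("item:"):])
    raise ExpressionError(f"unrecognized token {token!r}")


def parse_expression(
    text: str,
    model: Optional[OntologyModel] = None,
    operators: OperatorTable = DEFAULT_OPERATORS,
) -> ExpressionNode:
    """Parse and validate an s-expression; resolve references when a model is given."""
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression")
    pos = 0

    def read() -> ExpressionNode:
        nonlocal pos
        if pos >= len(tokens):
            raise ExpressionError("unexpected end of expression")
        token = tokens[pos]
        pos += 1
        if token == "(":
            if pos >= len(tokens) or tokens[pos] in ("(", ")"):
                raise ExpressionError("expected an operator after '('")
            op_name = tokens[pos]
            pos += 1
            args = []
            while pos < len(tokens) and tokens[pos] != ")":
                args.append(read())
            if pos >= len(tokens):
                raise ExpressionError("missing closing ')'")
            pos += 1  # consume ')'
            return ExpressionNode("relator", operator=op_name, args=args)
        if token == ")":
            raise ExpressionError("unexpected ')'")
        return _atom(token)

    tree = read()
    if pos != len(tokens):
        raise ExpressionError("trailing tokens after expression")
    validate_expression(tree, model=model, operators=operators)
    return tree


def _result_type(node: ExpressionNode, operators: OperatorTable) -> str:
    if node.node_kind == "relator":
        return operators.get(node.operator).result_type
    if node.node_kind == "number":
        return NUMERIC
    if node.node_kind == "boolean":
        return BOOLEAN
    return ANY  # references: type known only at evaluation time


def validate_expression(
    node: ExpressionNode,
    model: Optional[OntologyModel] = None,
    operators: OperatorTable = DEFAULT_OPERATORS,
) -> None:
    """Check arity and operand types throughout the tree; resolve references."""
    if node.node_kind == "relator":
        op = operators.get(node.operator)
        n = len(node.args)
        if n < op.min_arity or (op.max_arity is not None and n > op.max_arity):
            wanted = (
                str(op.min_arity)
                if op.max_arity == op.min_arity
                else f">= {op.min_arity}"
            )
            raise ExpressionError(
                f"operator {op.name!r} expects {wanted} argument(s), got {n}"
            )
        for arg in node.args:
            validate_expression(arg, model=model, operators=operators)
            got = _result_type(arg, operators)
            if op.operand_type != ANY and got not in (op.operand_type, ANY):
                raise ExpressionError(
                    f"operator {op.name!r} expects {op.operand_type} operands, "
                    f"got a {got} argument"
                )
    elif node.node_kind == "element_ref" and model is not None:
        inst = model.find_by_slot("_ELEMENT", "name", node.name) or model.find_by_slot(
            "_ELEMENT", ":NAME", node.name
        )
        if inst is None:
            raise ExpressionError(f"element reference item:{node.name} does not resolve")
        node.ref = inst.id
    elif node.node_kind == "constant_ref" and model is not None:
        inst = model.find_by_slot("_CONSTANT", "name", node.name)
        if inst is None:
            raise ExpressionError(f"constant reference const:{node.name} does not resolve")
        node.ref = inst.id


def serialize_expression(node: ExpressionNode) -> str:
    """Canonical s-expression text; ``parse ∘ serialize`` is the identity."""
    kind = node.node_kind
    if kind == "number":
        return repr(node.value)
    if kind == "boolean":
        return "true" if node.value else "false"
    if kind == "constant_ref":
        return f"const:{node.name}"
    if kind == "element_ref":
        return f"item:{node.name}"
    inner = " ".join(serialize_expression(a) for a in node.args)
    return f"({node.operator} {inner})"


def _as_number(value: Any, context: str) -> Any:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ExpressionError(f"{context}: expected a number, got {value!r}")
    return value


def _as_boolean(value: Any, context: str) -> bool:
    if not isinstance(value, bool):
        raise ExpressionError(f"{context}: expected a boolean, got {value!r}")
    return value


def evaluate_expression(
    node: ExpressionNode,
    bindings: Optional[dict] = None,
    constants: Optional[dict] = None,
    *,
    partial: bool = False,
    operators: OperatorTable = DEFAULT_OPERATORS,
) -> Any:
    """Bottom-up evaluation with strict two-valued booleans.

    ``bindings`` maps element names (or resolved instance ids) to values;
    ``constants`` likewise for constant references.  An unbound reference
    raises unless ``partial`` is set, in which case the subexpression — and
    anything depending on it — evaluates to ``None`` ("unknown"); AND/OR
    still short-circuit on a decisive known operand.
    """
    bindings = bindings or {}
    constants = constants or {}
    kind = node.node_kind
    if kind in ("number", "boolean"):
        return node.value
    if kind in ("element_ref", "constant_ref"):
        table = bindings if kind == "element_ref" else constants
        for key in (node.name, node.ref):
            if key is not None and key in table:
                return table[key]
        if partial:
            return None
        label = "item" if kind == "element_ref" else "const"
        raise ExpressionError(f"unbound reference {label}:{node.name}")

    op = operators.get(node.operator)
    args = [
        evaluate_expression(
            a, bindings, constants, partial=partial, operators=operators
        )
        for a in node.args
    ]
    name = op.name
    if name in ("AND", "OR"):
        decisive = (name == "OR")
        known = [_as_boolean(v, name) for v in args if v is not None]
        if decisive in known:
            return decisive
        if len(known) < len(args):
            return None  # unknown operands, none decisive
        return not decisive
    if name == "NOT":
        return None if args[0] is None else not _as_boolean(args[0], name)
    if None in args:
        return None
    if name == "=":
        return args[0] == args[1]
    nums = [_as_number(v, name) for v in args]
    if name == "+":
        return sum(nums)
    if name == "*":
        out = 1
        for v in nums:
            out *= v
        return out
    if name == "-":
        return nums[0] - nums[1]
    if name == "/":
        if nums[1] == 0:
            raise ExpressionError("division by zero")
        out = nums[0] / nums[1]
        if isinstance(nums[0], int) and isinstance(nums[1], int) and out.is_integer():
            return int(out)
        return out
    comparator = {
        ">": lambda a, b: a > b,
        "<": lambda a, b: a < b,
        ">=": lambda a, b: a >= b,
        "<=": lambda a, b: a <= b,
    }.get(name)
    if comparator is not None:
        return comparator(nums[0], nums[1])
    raise ExpressionError(f"operator {name!r} has no evaluation rule")
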