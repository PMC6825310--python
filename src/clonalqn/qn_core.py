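"""Qualitative-network (QN) engine.

A qualitative network generalizes a Boolean network: every node holds a
bounded integer activity level and, at each synchronous tick, moves one
step toward a real-valued *target function* of its inputs.  The default
target is ``avg(activators) - avg(inhibitors)``; a node with no activators
is assumed constitutively active and tends toward a per-node constant minus
the average of its inhibitors.  Custom targets are expression trees over
``var``, ``avg``, ``min``, ``max``, arithmetic, ``ceil`` and ``floor``.

Long-run behavior is analyzed two ways:

* exhaustive attractor enumeration (brute force over the full state space,
  only feasible for small engines/test models), and
* interval narrowing: iterative shrinking of per-node ``[lo, hi]`` bounds
  that soundly over-approximates every attractor; when all bounds collapse
  to points the network is proven to stabilize at that unique fixed point.

Nodes whose bounds do not collapse are summarized by the mean of the
minimum and maximum level they take across sampled attractors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Const",
    "Var",
    "Avg",
    "Unary",
    "Binary",
    "FormulaExpr",
    "VariableDef",
    "RelationshipDef",
    "QNModel",
    "Perturbation",
    "Attractor",
    "NodeSummary",
    "QNError",
    "QNModelError",
    "QNEvaluationError",
    "BudgetExceededError",
    "evaluate_formula",
    "target_value",
    "synchronous_step",
    "simulate",
    "enumerate_attractors",
    "narrow_intervals",
    "stabilize",
    "summarize_variable",
    "formula_support",
    "DEFAULT_BRUTE_FORCE_BOUND",
    "DEFAULT_SUPPORT_BUDGET",
    "DEFAULT_SAMPLE_COUNT",
]


class QNError(Exception):
    """Base class for engine errors."""


class QNModelError(QNError):
    """The model itself is malformed (dangling reference, bad range...)."""


class QNEvaluationError(QNError):
    """A target function could not be evaluated (e.g. division by zero)."""


class BudgetExceededError(QNError):
    """A configured computational budget was exceeded."""


# --------------------------------------------------------------------------
# Formula expression trees
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Const:
    value: float


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Avg:
    args: tuple


@dataclass(frozen=True)
class Unary:
    op: str  # "neg" | "ceil" | "floor"
    arg: object


@dataclass(frozen=True)
class Binary:
    op: str  # "+" | "-" | "*" | "/" | "min" | "max"
    left: object
    right: object


FormulaExpr = object  # union of the node classes above


def formula_support(expr) -> set:
    """Names of all variables referenced by ``expr``."""
    if isinstance(expr, Var):
        return {expr.name}
    if isinstance(expr, Const):
        return set()
    if isinstance(expr, Avg):
        out: set = set()
        for a in expr.args:
            out |= formula_support(a)
        return out
    if isinstance(expr, Unary):
        return formula_support(expr.arg)
    if isinstance(expr, Binary):
        return formula_support(expr.left) | formula_support(expr.right)
    raise QNModelError(f"unknown formula node {expr!r}")


# --------------------------------------------------------------------------
# Model containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableDef:
    """A network node.

    ``formula is None`` marks the default target function.  ``constitutive``
    is the constant a node with no activators tends toward (defaults to the
    top of its range: an unopposed receptor/ligand node is fully on).
    """

    id: int
    name: str
    range_min: int = 0
    range_max: int = 4
    formula: object | None = None
    constitutive: float | None = None
    pathway: str = ""
    druggable: bool = False

    def __post_init__(self):
        if self.range_min >= self.range_max:
            raise QNModelError(
                f"variable {self.name!r}: range_min must be < range_max"
            )
        const = self.constitutive
        if const is not None and not (self.range_min <= const <= self.range_max):
            raise QNModelError(
                f"variable {self.name!r}: constitutive constant {const} "
                f"outside range [{self.range_min}, {self.range_max}]"
            )

    @property
    def constitutive_const(self) -> float:
        return float(self.range_max if self.constitutive is None else self.constitutive)

    @property
    def n_levels(self) -> int:
        return self.range_max - self.range_min + 1


@dataclass(frozen=True)
class RelationshipDef:
    from_id: int
    to_id: int
    sign: str  # "activator" | "inhibitor"

    def __post_init__(self):
        if self.sign not in ("activator", "inhibitor"):
            raise QNModelError(f"relationship sign must be activator/inhibitor, got {self.sign!r}")


@dataclass(frozen=True)
class Perturbation:
    """A node held at a constant level.

    ``inhibit`` fixes the node at its range minimum (drug inhibition);
    ``force`` fixes it at an explicit level (e.g. an oncogene at maximum).
    """

    variable: str
    mode: str = "inhibit"  # "inhibit" | "force"
    level: int | None = None

    def __post_init__(self):
        if self.mode not in ("inhibit", "force"):
            raise QNModelError(f"perturbation mode must be inhibit/force, got {self.mode!r}")
        if self.mode == "force" and self.level is None:
            raise QNModelError("force perturbation requires a level")


@dataclass(frozen=True)
class Attractor:
    """A cycle of the deterministic synchronous dynamics (period >= 1)."""

    cycle: tuple  # tuple of states; each state a tuple of ints
    basin_witness: tuple

    @property
    def period(self) -> int:
        return len(self.cycle)

    @property
    def states(self) -> frozenset:
        return frozenset(self.cycle)

    def canonical(self) -> tuple:
        """Rotation-invariant representation (used for deduplication)."""
        best = min(range(len(self.cycle)), key=lambda i: self.cycle[i:] + self.cycle[:i])
        return self.cycle[best:] + self.cycle[:best]


@dataclass(frozen=True)
class NodeSummary:
    min: int
    max: int

    @property
    def midpoint(self) -> float:
        return (self.min + self.max) / 2.0

    def __post_init__(self):
        if self.min > self.max:
            raise QNModelError("NodeSummary min must be <= max")


DEFAULT_BRUTE_FORCE_BOUND = 10 ** 6
DEFAULT_SUPPORT_BUDGET = 10 ** 5
DEFAULT_SAMPLE_COUNT = 32


class QNModel:
    """A validated qualitative network.

    Keeps variables ordered by id and precomputes, per variable, its
    activator/inhibitor input lists and a fast evaluator of its target
    function.
    """

    def __init__(self, variables: Sequence[VariableDef], relationships: Sequence[RelationshipDef], name: str = "qn"):
        self.name = name
        self.variables: tuple = tuple(sorted(variables, key=lambda v: v.id))
        self.relationships: tuple = tuple(relationships)
        ids = [v.id for v in self.variables]
        if len(set(ids)) != len(ids):
            raise QNModelError("variable ids must be unique")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise QNModelError("variable names must be unique")
        self.by_id: dict = {v.id: v for v in self.variables}
        self.by_name: dict = {v.name: v for v in self.variables}
        self.index: dict = {v.id: i for i, v in enumerate(self.variables)}

        seen = set()
        for r in self.relationships:
            if r.from_id not in self.by_id:
                raise QNModelError(f"relationship references unknown source variable id {r.from_id}")
            if r.to_id not in self.by_id:
                raise QNModelError(f"relationship references unknown target variable id {r.to_id}")
            key = (r.from_id, r.to_id, r.sign)
            if key in seen:
                raise QNModelError(f"duplicate relationship {key}")
            seen.add(key)

        # per-variable input index lists, in id order for determinism
        self.activators: list = [[] for _ in self.variables]
        self.inhibitors: list = [[] for _ in self.variables]
        for r in sorted(self.relationships, key=lambda r: (r.to_id, r.from_id, r.sign)):
            tgt = self.index[r.to_id]
            src = self.index[r.from_id]
            if r.sign == "activator":
                self.activators[tgt].append(src)
            else:
                self.inhibitors[tgt].append(src)

        # validate formulas: every var() reference must name an existing
        # variable with a relationship into the formula's owner
        for i, v in enumerate(self.variables):
            if v.formula is None:
                continue
            inputs = {self.variables[j].name for j in self.activators[i] + self.inhibitors[i]}
            for ref in formula_support(v.formula):
                if ref not in self.by_name:
                    raise QNModelError(
                        f"formula of {v.name!r} references unknown variable {ref!r}"
                    )
                if ref not in inputs:
                    raise QNModelError(
                        f"formula of {v.name!r} references {ref!r}, which has no "
                        f"relationship into {v.name!r}"
                    )

        self._evaluators: list | None = None

    # -- convenience ------------------------------------------------------

    def variable(self, ref) -> VariableDef:
        if isinstance(ref, VariableDef):
            return ref
        if isinstance(ref, int):
            try:
                return self.by_id[ref]
            except KeyError:
                raise QNModelError(f"no variable with id {ref}") from None
        try:
            return self.by_name[ref]
        except KeyError:
            raise QNModelError(f"no variable named {ref!r}") from None

    @property
    def n(self) -> int:
        return len(self.variables)

    def state_space_size(self) -> int:
        size = 1
        for v in self.variables:
            size *= v.n_levels
        return size

    def full_box(self) -> dict:
        return {v.id: (v.range_min, v.range_max) for v in self.variables}

    def total_levels(self) -> int:
        return sum(v.n_levels for v in self.variables)

    def with_name(self, name: str) -> "QNModel":
        return QNModel(self.variables, self.relationships, name=name)

    # -- target evaluation ------------------------------------------------

    def _rescale(self, level: float, src: VariableDef, dst: VariableDef) -> float:
        """Map a source level onto the consumer's range (identity when equal)."""
        if src.range_min == dst.range_min and src.range_max == dst.range_max:
            return float(level)
        span_s = src.range_max - src.range_min
        span_d = dst.range_max - dst.range_min
        return dst.range_min + (level - src.range_min) * span_d / span_s

    def evaluators(self) -> list:
        """One ``f(state_tuple) -> float`` per variable (unclamped target)."""
        if self._evaluators is None:
            self._evaluators = [self._compile_target(i) for i in range(self.n)]
        return self._evaluators

    def _compile_target(self, i: int) -> Callable:
        v = self.variables[i]
        if v.formula is not None:
            return self._compile_expr(v.formula, v)
        acts = self.activators[i]
        inhs = self.inhibitors[i]
        uniform = all(
            self.variables[j].range_min == v.range_min
            and self.variables[j].range_max == v.range_max
            for j in acts + inhs
        )
        if uniform:
            if acts:
                na, ni = float(len(acts)), float(len(inhs))
                if inhs:
                    def ev(s, acts=tuple(acts), inhs=tuple(inhs), na=na, ni=ni):
                        return sum(s[j] for j in acts) / na - sum(s[j] for j in inhs) / ni
                else:
                    def ev(s, acts=tuple(acts), na=na):
                        return sum(s[j] for j in acts) / na
            else:
                const = v.constitutive_const
                if inhs:
                    ni = float(len(inhs))
                    def ev(s, inhs=tuple(inhs), const=const, ni=ni):
                        return const - sum(s[j] for j in inhs) / ni
                else:
                    def ev(s, const=const):
                        return const
            return ev

        # heterogeneous ranges: rescale each input onto the consumer's range
        def ev(s, acts=tuple(acts), inhs=tuple(inhs), v=v):
            if acts:
                pos = sum(self._rescale(s[j], self.variables[j], v) for j in acts) / len(acts)
            else:
                pos = v.constitutive_const
            neg = (
                sum(self._rescale(s[j], self.variables[j], v) for j in inhs) / len(inhs)
                if inhs
                else 0.0
            )
            return pos - neg

        return ev

    def _compile_expr(self, expr, owner: VariableDef) -> Callable:
        if isinstance(expr, Const):
            val = float(expr.value)
            return lambda s: val
        if isinstance(expr, Var):
            src = self.variable(expr.name)
            j = self.index[src.id]
            if src.range_min == owner.range_min and src.range_max == owner.range_max:
                return lambda s: float(s[j])
            return lambda s, src=src: self._rescale(s[j], src, owner)
        if isinstance(expr, Avg):
            subs = [self._compile_expr(a, owner) for a in expr.args]
            if not subs:
                return lambda s: 0.0
            n = float(len(subs))
            return lambda s: sum(f(s) for f in subs) / n
        if isinstance(expr, Unary):
            f = self._compile_expr(expr.arg, owner)
            if expr.op == "neg":
                return lambda s: -f(s)
            if expr.op == "ceil":
                return lambda s: float(math.ceil(f(s)))
            if expr.op == "floor":
                return lambda s: float(math.floor(f(s)))
            raise QNModelError(f"unknown unary op {expr.op!r}")
        if isinstance(expr, Binary):
            a = self._compile_expr(expr.left, owner)
            b = self._compile_expr(expr.right, owner)
            op = expr.op
            if op == "+":
                return lambda s: a(s) + b(s)
            if op == "-":
                return lambda s: a(s) - b(s)
            if op == "*":
                return lambda s: a(s) * b(s)
            if op == "/":
                name = owner.name

                def div(s):
                    d = b(s)
                    if d == 0:
                        raise QNEvaluationError(
                            f"division by zero while evaluating target of {name!r}"
                        )
                    return a(s) / d

                return div
            if op == "min":
                return lambda s: min(a(s), b(s))
            if op == "max":
                return lambda s: max(a(s), b(s))
            raise QNModelError(f"unknown binary op {op!r}")
        raise QNModelError(f"unknown formula node {expr!r}")


# --------------------------------------------------------------------------
# Evaluation & dynamics
# --------------------------------------------------------------------------

def _as_state_tuple(model: QNModel, s) -> tuple:
    if isinstance(s, tuple):
        if len(s) != model.n:
            raise QNModelError("state has wrong length")
        return s
    if isinstance(s, Mapping):
        out = []
        for v in model.variables:
            if v.id in s:
                out.append(int(s[v.id]))
            elif v.name in s:
                out.append(int(s[v.name]))
            else:
                raise QNModelError(f"state missing variable {v.name!r}")
        return tuple(out)
    raise QNModelError(f"cannot interpret state {s!r}")


def _check_state(model: QNModel, s: tuple) -> None:
    for v, lvl in zip(model.variables, s):
        if not (v.range_min <= lvl <= v.range_max):
            raise QNModelError(f"level {lvl} of {v.name!r} out of range")


def evaluate_formula(expr, state, model: QNModel, owner: VariableDef | None = None) -> float:
    """Evaluate an expression tree under a state.  The result is NOT clamped.

    ``owner`` (the variable the formula belongs to) enables input rescaling
    for heterogeneous ranges; without it raw levels are used.
    """
    s = _as_state_tuple(model, state)
    if owner is None:
        return _eval_raw(expr, s, model)
    return model._compile_expr(expr, owner)(s)


def _eval_raw(expr, s: tuple, model: QNModel) -> float:
    if isinstance(expr, Const):
        return float(expr.value)
    if isinstance(expr, Var):
        src = model.variable(expr.name)
        return float(s[model.index[src.id]])
    if isinstance(expr, Avg):
        if not expr.args:
            return 0.0
        return sum(_eval_raw(a, s, model) for a in expr.args) / len(expr.args)
    if isinstance(expr, Unary):
        x = _eval_raw(expr.arg, s, model)
        if expr.op == "neg":
            return -x
        if expr.op == "ceil":
            return float(math.ceil(x))
        if expr.op == "floor":
            return float(math.floor(x))
    if isinstance(expr, Binary):
        a = _eval_raw(expr.left, s, model)
        b = _eval_raw(expr.right, s, model)
        if expr.op == "+":
            return a + b
        if expr.op == "-":
            return a - b
        if expr.op == "*":
            return a * b
        if expr.op == "/":
            if b == 0:
                raise QNEvaluationError("division by zero in formula evaluation")
            return a / b
        if expr.op == "min":
            return min(a, b)
        if expr.op == "max":
            return max(a, b)
    raise QNModelError(f"unknown formula node {expr!r}")


def target_value(v, state, model: QNModel) -> float:
    """The (clamped) level variable ``v`` tends toward under ``state``."""
    v = model.variable(v)
    s = _as_state_tuple(model, state)
    raw = model.evaluators()[model.index[v.id]](s)
    return min(max(raw, float(v.range_min)), float(v.range_max))


def _normalize_perturbations(model: QNModel, perturbs) -> dict:
    """Map perturbations to {variable index: fixed level}."""
    fixed: dict = {}
    for p in perturbs or ():
        v = model.variable(p.variable)
        if p.mode == "inhibit":
            lvl = v.range_min
        else:
            lvl = int(p.level)
            if not (v.range_min <= lvl <= v.range_max):
                raise QNModelError(
                    f"forced level {lvl} outside range of {v.name!r}"
                )
        i = model.index[v.id]
        if i in fixed and fixed[i] != lvl:
            raise QNModelError(f"conflicting perturbations on {v.name!r}")
        fixed[i] = lvl
    return fixed


def synchronous_step(state, model: QNModel, perturbs=()) -> tuple:
    """One simultaneous update: every free node moves one level toward its
    target (computed on the *current* state); fixed nodes keep their level."""
    s = _as_state_tuple(model, state)
    _check_state(model, s)
    fixed = perturbs if isinstance(perturbs, dict) else _normalize_perturbations(model, perturbs)
    evs = model.evaluators()
    nxt = list(s)
    for i, v in enumerate(model.variables):
        if i in fixed:
            nxt[i] = fixed[i]
            continue
        t = evs[i](s)
        cur = s[i]
        if t > cur and cur < v.range_max:
            nxt[i] = cur + 1
        elif t < cur and cur > v.range_min:
            nxt[i] = cur - 1
    return tuple(nxt)


def simulate(s0, model: QNModel, perturbs=(), max_steps: int | None = None):
    """Iterate the synchronous dynamics until a state repeats.

    Returns ``(trajectory, attractor)`` where the trajectory runs from the
    initial state up to (and including) the first revisited state and the
    attractor is the closed cycle.  Deterministic dynamics over a finite
    space guarantee termination; exceeding ``max_steps`` raises rather than
    silently truncating.
    """
    if max_steps is None:
        max_steps = 10 * model.total_levels()
    if max_steps < 1:
        raise QNModelError("max_steps must be >= 1")
    fixed = _normalize_perturbations(model, perturbs)
    s = _as_state_tuple(model, s0)
    # apply fixings to the initial state so the trajectory starts inside
    # the perturbed subspace
    if fixed:
        s = tuple(fixed.get(i, lvl) for i, lvl in enumerate(s))
    _check_state(model, s)
    seen = {s: 0}
    traj = [s]
    for _ in range(max_steps):
        s = synchronous_step(s, model, fixed)
        traj.append(s)
        if s in seen:
            start = seen[s]
            cycle = tuple(traj[start:-1])
            return traj, Attractor(cycle=cycle, basin_witness=traj[0])
        seen[s] = len(traj) - 1
    raise BudgetExceededError(
        f"no cycle closed within {max_steps} steps (model {model.name!r})"
    )


def enumerate_attractors(model: QNModel, perturbs=(), bound: int = DEFAULT_BRUTE_FORCE_BOUND):
    """Brute-force attractor enumeration over the entire state space.

    Simulates from every state (memoizing basins) and returns the set of
    distinct attractors; the union of their states is exactly the set of
    recurrent states.
    """
    size = model.state_space_size()
    if size > bound:
        raise BudgetExceededError(
            f"state space has {size} states, above the configured bound {bound}"
        )
    fixed = _normalize_perturbations(model, perturbs)
    ranges = []
    for i, v in enumerate(model.variables):
        if i in fixed:
            ranges.append((fixed[i],))
        else:
            ranges.append(tuple(range(v.range_min, v.range_max + 1)))

    basin: dict = {}  # state -> canonical cycle key
    attractors: dict = {}  # canonical cycle key -> Attractor
    for s0 in itertools.product(*ranges):
        if s0 in basin:
            continue
        path = []
        s = s0
        while s not in basin:
            path.append(s)
            s = synchronous_step(s, model, fixed)
            if s in path:  # new cycle closed within this path
                start = path.index(s)
                cyc = Attractor(cycle=tuple(path[start:]), basin_witness=s0)
                key = cyc.canonical()
                if key not in attractors:
                    attractors[key] = cyc
                for st in path:
                    basin[st] = key
                break
        else:
            key = basin[s]
            for st in path:
                basin[st] = key
    return set(attractors.values())


# --------------------------------------------------------------------------
# Interval narrowing
# --------------------------------------------------------------------------

def _interval_eval(expr, box_by_name: Mapping, model: QNModel, owner: VariableDef):
    """Conservative interval arithmetic over an expression tree.

    Exact (monotonicity-aware) for avg/min/max/+/-/neg/ceil/floor; widening
    for * and / (all sign combinations considered; a divisor interval
    containing zero is an evaluation error, mirroring point semantics).
    """
    if isinstance(expr, Const):
        return (float(expr.value), float(expr.value))
    if isinstance(expr, Var):
        lo, hi = box_by_name[expr.name]
        src = model.variable(expr.name)
        return (model._rescale(lo, src, owner), model._rescale(hi, src, owner))
    if isinstance(expr, Avg):
        if not expr.args:
            return (0.0, 0.0)
        los, his = zip(*(_interval_eval(a, box_by_name, model, owner) for a in expr.args))
        return (sum(los) / len(los), sum(his) / len(his))
    if isinstance(expr, Unary):
        lo, hi = _interval_eval(expr.arg, box_by_name, model, owner)
        if expr.op == "neg":
            return (-hi, -lo)
        if expr.op == "ceil":
            return (float(math.ceil(lo)), float(math.ceil(hi)))
        if expr.op == "floor":
            return (float(math.floor(lo)), float(math.floor(hi)))
    if isinstance(expr, Binary):
        alo, ahi = _interval_eval(expr.left, box_by_name, model, owner)
        blo, bhi = _interval_eval(expr.right, box_by_name, model, owner)
        if expr.op == "+":
            return (alo + blo, ahi + bhi)
        if expr.op == "-":
            return (alo - bhi, ahi - blo)
        if expr.op == "min":
            return (min(alo, blo), min(ahi, bhi))
        if expr.op == "max":
            return (max(alo, blo), max(ahi, bhi))
        if expr.op == "*":
            prods = (alo * blo, alo * bhi, ahi * blo, ahi * bhi)
            return (min(prods), max(prods))
        if expr.op == "/":
            if blo <= 0 <= bhi:
                raise QNEvaluationError(
                    f"possible division by zero in target of {owner.name!r}"
                )
            quots = (alo / blo, alo / bhi, ahi / blo, ahi / bhi)
            return (min(quots), max(quots))
    raise QNModelError(f"unknown formula node {expr!r}")


def _target_range(model: QNModel, i: int, box: Mapping, support_budget: int):
    """Exact [tmin, tmax] of variable i's target over the box, enumerated
    over the support; conservative interval arithmetic past the budget."""
    v = model.variables[i]
    acts, inhs = model.activators[i], model.inhibitors[i]
    if v.formula is None:
        # avg(pos) - avg(neg) is monotone: endpoint evaluation is exact
        if acts:
            pos_lo = sum(model._rescale(box[model.variables[j].id][0], model.variables[j], v) for j in acts) / len(acts)
            pos_hi = sum(model._rescale(box[model.variables[j].id][1], model.variables[j], v) for j in acts) / len(acts)
        else:
            pos_lo = pos_hi = v.constitutive_const
        if inhs:
            neg_lo = sum(model._rescale(box[model.variables[j].id][0], model.variables[j], v) for j in inhs) / len(inhs)
            neg_hi = sum(model._rescale(box[model.variables[j].id][1], model.variables[j], v) for j in inhs) / len(inhs)
        else:
            neg_lo = neg_hi = 0.0
        return (pos_lo - neg_hi, pos_hi - neg_lo)

    support = sorted(formula_support(v.formula))
    combos = 1
    for name in support:
        lo, hi = box[model.by_name[name].id]
        combos *= hi - lo + 1
    if combos > support_budget:
        box_by_name = {u.name: box[u.id] for u in model.variables}
        return _interval_eval(v.formula, box_by_name, model, v)

    ev = model._compile_expr(v.formula, v)
    idxs = [model.index[model.by_name[name].id] for name in support]
    base = [box[u.id][0] for u in model.variables]  # non-support values irrelevant
    tmin, tmax = math.inf, -math.inf
    ranges = [range(box[model.by_name[name].id][0], box[model.by_name[name].id][1] + 1) for name in support]
    state = list(base)
    for combo in itertools.product(*ranges):
        for k, j in enumerate(idxs):
            state[j] = combo[k]
        t = ev(state)
        if t < tmin:
            tmin = t
        if t > tmax:
            tmax = t
    return (tmin, tmax)


def narrow_intervals(
    model: QNModel,
    perturbs=(),
    box0: Mapping | None = None,
    support_budget: int = DEFAULT_SUPPORT_BUDGET,
    order: Sequence | None = None,
) -> dict:
    """Shrink per-variable [lo, hi] bounds to a fixpoint.

    For each free variable the exact target range over the current box is
    computed and the interval replaced by
    ``[clamp(floor(tmin)), clamp(ceil(tmax))]``; iteration proceeds
    round-robin in id order (or the given ``order`` of variable ids, which
    can only affect speed, not the fixpoint) until a full pass changes
    nothing.  Every
    attractor reachable from within ``box0`` lies inside the returned box;
    if all intervals are points, the point is a fixed point of the
    synchronous step.
    """
    box = dict(box0) if box0 is not None else model.full_box()
    for v in model.variables:
        lo, hi = box[v.id]
        if not (v.range_min <= lo <= hi <= v.range_max):
            raise QNModelError(f"box for {v.name!r} outside variable range")
    fixed = _normalize_perturbations(model, perturbs)
    for i, lvl in fixed.items():
        box[model.variables[i].id] = (lvl, lvl)

    # Round-robin Kleene iteration.  From the full box the per-variable
    # intervals shrink monotonically (a smaller box can only narrow each
    # target range), so the loop terminates; a pass cap guards the general
    # sub-box entry point.
    if order is None:
        sweep = list(range(model.n))
    else:
        sweep = [model.index[model.variable(ref).id] for ref in order]
        if sorted(sweep) != list(range(model.n)):
            raise QNModelError("order must be a permutation of all variables")
    max_passes = 10 * model.total_levels() + 10
    for _ in range(max_passes):
        changed = False
        for i in sweep:
            v = model.variables[i]
            if i in fixed:
                continue
            tmin, tmax = _target_range(model, i, box, support_budget)
            # a node steps toward its target, so recurrent levels are
            # confined to [floor(tmin), ceil(tmax)] clamped to the range
            lo = int(min(max(math.floor(tmin), v.range_min), v.range_max))
            hi = int(min(max(math.ceil(tmax), v.range_min), v.range_max))
            if (lo, hi) != box[v.id]:
                box[v.id] = (lo, hi)
                changed = True
        if not changed:
            return box
    raise BudgetExceededError("interval narrowing did not reach a fixpoint")


def _is_point_box(box: Mapping) -> bool:
    return all(lo == hi for lo, hi in box.values())


def stabilize(
    model: QNModel,
    perturbs=(),
    seed: int = 0,
    samples: int = DEFAULT_SAMPLE_COUNT,
    max_steps: int | None = None,
):
    """Narrow intervals and summarize every node's long-run behavior.

    Returns ``(box, summaries, proven_stable)`` where ``summaries`` maps
    variable name to :class:`NodeSummary`.  When the box collapses to a
    point the network is proven to stabilize there.  Otherwise nodes are
    summarized over the union of attractors reached from a deterministic
    sample of initial states inside the box (both corners, the midpoint,
    and ``samples`` seeded draws).
    """
    import numpy as np

    box = narrow_intervals(model, perturbs)
    if _is_point_box(box):
        summaries = {
            v.name: NodeSummary(box[v.id][0], box[v.id][0]) for v in model.variables
        }
        return box, summaries, True

    los = tuple(box[v.id][0] for v in model.variables)
    his = tuple(box[v.id][1] for v in model.variables)
    mids = tuple((lo + hi) // 2 for lo, hi in zip(los, his))
    starts = [los, his, mids]
    rng = np.random.default_rng(seed)
    for _ in range(samples):
        starts.append(
            tuple(int(rng.integers(lo, hi + 1)) for lo, hi in zip(los, his))
        )

    union_min = list(his)
    union_max = list(los)
    seen_cycles = set()
    for s0 in starts:
        _, att = simulate(s0, model, perturbs, max_steps=max_steps)
        key = att.canonical()
        if key in seen_cycles:
            continue
        seen_cycles.add(key)
        for st in att.cycle:
            for i, lvl in enumerate(st):
                if lvl < union_min[i]:
                    union_min[i] = lvl
                if lvl > union_max[i]:
                    union_max[i] = lvl
    summaries = {
        v.name: NodeSummary(union_min[i], union_max[i])
        for i, v in enumerate(model.variables)
    }
    return box, summaries, False


def summarize_variable(
    model: QNModel,
    perturbs,
    v,
    seed: int = 0,
    samples: int = DEFAULT_SAMPLE_COUNT,
) -> NodeSummary:
    """Long-run summary of one node: its [min, max] across attractors and
    the mean of the two (the midpoint convention for oscillating nodes)."""
    v = model.variable(v)
    _, summaries, _ = stabilize(model, perturbs, seed=seed, samples=samples)
    return summaries[v.name]
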