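"""A deliberately naive, independent re-implementation of the QN step
semantics, used only as a cross-check oracle in tests.

It shares no code with the engine: states are dicts keyed by variable
name, targets are computed by direct recursion over the definition, and
attractors are found by plain iteration.
"""

import math
from fractions import Fraction


def _target(model, name, state):
    v = model.by_name[name]
    if v.formula is not None:
        t = _eval(model, v.formula, state)
    else:
        i = model.index[v.id]
        acts = [model.variables[j].name for j in model.activators[i]]
        inhs = [model.variables[j].name for j in model.inhibitors[i]]
        if acts:
            pos = Fraction(sum(state[a] for a in acts), len(acts))
        else:
            pos = Fraction(v.constitutive_const)
        neg = Fraction(sum(state[a] for a in inhs), len(inhs)) if inhs else Fraction(0)
        t = pos - neg
    return min(max(t, Fraction(v.range_min)), Fraction(v.range_max))


def _eval(model, expr, state):
    from clonalqn.qn_core import Avg, Binary, Const, Unary, Var

    if isinstance(expr, Const):
        return Fraction(expr.value)
    if isinstance(expr, Var):
        return Fraction(state[expr.name])
    if isinstance(expr, Avg):
        return Fraction(sum(_eval(model, a, state) for a in expr.args), len(expr.args))
    if isinstance(expr, Unary):
        x = _eval(model, expr.arg, state)
        return {"neg": -x, "ceil": Fraction(math.ceil(x)), "floor": Fraction(math.floor(x))}[expr.op]
    if isinstance(expr, Binary):
        a = _eval(model, expr.left, state)
        b = _eval(model, expr.right, state)
        if expr.op == "+":
            return a + b
        if expr.op == "-":
            return a - b
        if expr.op == "*":
            return a * b
        if expr.op == "/":
            return a / b
        if expr.op == "min":
            return min(a, b)
        if expr.op == "max":
            return max(a, b)
    raise AssertionError(f"unknown node {expr!r}")


def naive_step(model, state, fixed=None):
    """state: dict name -> level.  fixed: dict name -> level."""
    fixed = fixed or {}
    nxt = {}
    for v in model.variables:
        if v.name in fixed:
            nxt[v.name] = fixed[v.name]
            continue
        t = _target(model, v.name, state)
        cur = state[v.name]
        if t > cur:
            nxt[v.name] = min(cur + 1, v.range_max)
        elif t < cur:
            nxt[v.name] = max(cur - 1, v.range_min)
        else:
            nxt[v.name] = cur
    return nxt


def naive_attractor(model, state0, fixed=None, limit=100000):
    """Iterate until a state repeats; return the cycle as a set of
    name->level dict snapshots frozen into sorted tuples."""
    fixed = fixed or {}
    state = dict(state0)
    state.update(fixed)
    seen = {}
    traj = []
    for k in range(limit):
        key = tuple(sorted(state.items()))
        if key in seen:
            return traj[seen[key]:]
        seen[key] = k
        traj.append(key)
        state = naive_step(model, state, fixed)
    raise AssertionError("no cycle within limit")


def naive_all_attractors(model, fixed=None):
    """Exhaustive enumeration; returns a set of frozensets of state keys."""
    import itertools

    fixed = fixed or {}
    ranges = []
    names = [v.name for v in model.variables]
    for v in model.variables:
        if v.name in fixed:
            ranges.append((fixed[v.name],))
        else:
            ranges.append(tuple(range(v.range_min, v.range_max + 1)))
    out = set()
    for combo in itertools.product(*ranges):
        state0 = dict(zip(names, combo))
        cyc = naive_attractor(model, state0, fixed)
        out.add(frozenset(cyc))
    return out
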