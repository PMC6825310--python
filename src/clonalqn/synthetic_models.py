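"""Seeded random QN generators and hand-built fixtures.

The random generator emits signed Erdős–Rényi digraphs with default
target functions; it exists so the engine and the screen can be exercised
(and brute-force-validated) without any curated model file.  The fixtures
are tiny networks whose complete attractor structure is known in closed
form, used as oracles throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qn_core import Const, QNModel, RelationshipDef, VariableDef

__all__ = ["GeneratorConfig", "random_qn", "fixtures", "Fixture"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_variables: int = 4
    edge_probability: float = 0.5
    activator_fraction: float = 0.5
    range_max: int = 2
    constitutive: float | None = None  # None -> engine default (range_max)
    seed: int = 0

    def __post_init__(self):
        if self.n_variables < 1:
            raise ValueError("n_variables must be >= 1")
        if not (0.0 <= self.edge_probability <= 1.0):
            raise ValueError("edge_probability must be in [0, 1]")
        if not (0.0 <= self.activator_fraction <= 1.0):
            raise ValueError("activator_fraction must be in [0, 1]")


def random_qn(cfg: GeneratorConfig) -> QNModel:
    """A reproducible random QN: same config + seed -> identical model."""
    rng = np.random.default_rng(cfg.seed)
    variables = [
        VariableDef(
            id=i + 1,
            name=f"N{i + 1}",
            range_min=0,
            range_max=cfg.range_max,
            constitutive=cfg.constitutive,
        )
        for i in range(cfg.n_variables)
    ]
    relationships = []
    for src in variables:
        for dst in variables:
            if rng.random() < cfg.edge_probability:
                sign = "activator" if rng.random() < cfg.activator_fraction else "inhibitor"
                relationships.append(RelationshipDef(src.id, dst.id, sign))
    return QNModel(
        variables,
        relationships,
        name=f"random_qn(n={cfg.n_variables},p={cfg.edge_probability},seed={cfg.seed})",
    )


@dataclass(frozen=True)
class Fixture:
    model: QNModel
    # expected attractors: frozenset of cycles, each cycle a tuple of states
    # in canonical rotation (see Attractor.canonical)
    attractors: frozenset
    note: str = ""


def _canon(cycle):
    best = min(range(len(cycle)), key=lambda i: cycle[i:] + cycle[:i])
    return tuple(cycle[best:] + cycle[:best])


def fixtures() -> dict:
    """Named fixtures with analytically known attractor sets."""
    out: dict = {}

    # 1. constant chain: A tends to 3, B copies A -> unique fixed point (3, 3)
    chain = QNModel(
        [
            VariableDef(1, "A", 0, 4, formula=Const(3.0)),
            VariableDef(2, "B", 0, 4),
        ],
        [RelationshipDef(1, 2, "activator")],
        name="constant_chain",
    )
    out["constant_chain"] = Fixture(
        chain,
        frozenset({_canon([(3, 3)])}),
        "feed-forward chain settles at the constant target",
    )

    # 2. fractional oscillator: target 2.5 is unreachable by integer levels,
    #    forcing the two-cycle 2 <-> 3 (summary midpoint 2.5)
    osc = QNModel(
        [VariableDef(1, "Osc", 0, 4, formula=Const(2.5))],
        [],
        name="fractional_oscillator",
    )
    out["fractional_oscillator"] = Fixture(
        osc,
        frozenset({_canon([(2,), (3,)])}),
        "fractional target forces an oscillation between levels 2 and 3",
    )

    # 3. mutual-inhibition toggle: X = 4 - Y, Y = 4 - X; every antidiagonal
    #    point is fixed
    toggle = QNModel(
        [
            VariableDef(1, "X", 0, 4, constitutive=4),
            VariableDef(2, "Y", 0, 4, constitutive=4),
        ],
        [
            RelationshipDef(1, 2, "inhibitor"),
            RelationshipDef(2, 1, "inhibitor"),
        ],
        name="toggle",
    )
    # The antidiagonal x + y = 4 is pointwise fixed; in addition the
    # synchronous step admits four period-2 "swap" cycles that straddle it
    # (e.g. (0,3) <-> (1,4)), since both nodes overshoot simultaneously.
    toggle_attractors = {_canon([(x, 4 - x)]) for x in range(5)}
    toggle_attractors |= {
        _canon([(x, 3 - x), (x + 1, 4 - x)]) for x in range(4)
    }
    out["toggle"] = Fixture(
        toggle,
        frozenset(toggle_attractors),
        "five antidiagonal fixed points plus four straddling two-cycles",
    )

    # 4. three-node negative-feedback ring over range 0..2:
    #    A = 2 - C, B = A, C = B.  One fixed point (1,1,1) plus two
    #    six-cycles; all verified by exhaustive enumeration in the tests.
    ring = QNModel(
        [
            VariableDef(1, "A", 0, 2, constitutive=2),
            VariableDef(2, "B", 0, 2),
            VariableDef(3, "C", 0, 2),
        ],
        [
            RelationshipDef(3, 1, "inhibitor"),
            RelationshipDef(1, 2, "activator"),
            RelationshipDef(2, 3, "activator"),
        ],
        name="negative_feedback_ring",
    )
    outer_cycle = [
        (1, 0, 0),
        (2, 1, 0),
        (2, 2, 1),
        (1, 2, 2),
        (0, 1, 2),
        (0, 0, 1),
    ]
    inner_cycle = [
        (2, 1, 1),
        (1, 2, 1),
        (1, 1, 2),
        (0, 1, 1),
        (1, 0, 1),
        (1, 1, 0),
    ]
    out["negative_feedback_ring"] = Fixture(
        ring,
        frozenset({_canon([(1, 1, 1)]), _canon(outer_cycle), _canon(inner_cycle)}),
        "delayed negative feedback: a fixed point and two rotating six-cycles",
    )
    return out
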