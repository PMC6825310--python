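"""Exhaustive single and pairwise in-silico inhibition screening.

Drug inhibition is modeled by fixing a node at its range minimum on top of
the clone's own node fixings; each condition is stabilized and the
proliferation and apoptosis phenotype nodes are summarized by the mean of
their minimum and maximum long-run levels.  Downstream analyses apply the
screening filters:

* treatments whose predicted apoptosis in healthy cells exceeds level 3
  are masked as toxic (strictly above 3; a midpoint of exactly 3 is kept);
* same-node "pairs" are rejected outright (treatments are sets);
* the change matrices quantify what adding a second inhibitor contributes
  on top of an effective monotherapy, averaged over the two tumor clones
  of the mixed-tumor context.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bma_io import serialize_model_text
from .qn_core import NodeSummary, Perturbation, QNModel, QNModelError, stabilize

__all__ = [
    "ConditionResult",
    "ScreenTable",
    "DeltaMatrix",
    "evaluate_condition",
    "run_screen",
    "healthy_toxicity_filter",
    "effective_monotherapies",
    "delta_matrix",
    "export_table",
    "export_matrix",
    "MIXED_TUMOR_CLONES",
    "OUTCOME_MARGIN",
]

#: the two tumor clones of the mixed-tumor (biclonal) context, used for
#: "mean change across both clones"
MIXED_TUMOR_CLONES = ("myc_high_mixed", "myc_low_mixed")

#: outcome label margin: |apoptosis - proliferation| midpoint difference
#: below this is called balanced
OUTCOME_MARGIN = 0.5

PROLIFERATION = "Proliferation"
APOPTOSIS = "Apoptosis"


@dataclass(frozen=True)
class ConditionResult:
    clone: str
    treatment: tuple  # sorted tuple of inhibited variable names (len <= 2)
    proliferation: NodeSummary
    apoptosis: NodeSummary

    @property
    def outcome(self) -> str:
        d = self.apoptosis.midpoint - self.proliferation.midpoint
        if d > OUTCOME_MARGIN:
            return "net_apoptosis"
        if d < -OUTCOME_MARGIN:
            return "net_proliferation"
        return "balanced"


@dataclass(frozen=True)
class ScreenTable:
    data: pd.DataFrame  # one row per (clone, treatment)
    provenance: dict

    def row(self, clone: str, treatment) -> pd.Series:
        key = "+".join(sorted(treatment))
        sel = self.data[(self.data["clone"] == clone) & (self.data["treatment"] == key)]
        if sel.empty:
            raise KeyError(f"no row for clone {clone!r}, treatment {key!r}")
        return sel.iloc[0]

    def midpoint(self, clone: str, treatment, metric: str) -> float:
        return float(self.row(clone, treatment)[f"{metric}_mid"])


@dataclass(frozen=True)
class DeltaMatrix:
    metric: str
    values: pd.DataFrame  # rows: first inhibitor; columns: added inhibitor
    mask: pd.DataFrame    # reason string, "" where the cell is valid
    clones: tuple

    def masked_values(self) -> pd.DataFrame:
        return self.values.where(self.mask == "")

    def argmax(self):
        """(first, added, value) of the maximal unmasked cell."""
        stacked = self.masked_values().stack()
        if stacked.empty:
            raise ValueError("all cells are masked")
        (a, b), v = max(stacked.items(), key=lambda kv: (kv[1], kv[0]))
        return a, b, float(v)


def _treatment_tuple(treatment) -> tuple:
    if isinstance(treatment, str):
        treatment = (treatment,)
    names = list(treatment)
    if len(set(names)) != len(names):
        raise QNModelError(
            f"a treatment is a set of distinct nodes; duplicate in {names!r} "
            "(inhibiting the same node twice is nonsensical)"
        )
    if len(names) > 2:
        raise QNModelError("treatments are single inhibitors or unordered pairs")
    return tuple(sorted(names))


def evaluate_condition(
    model: QNModel,
    clone,
    treatment=(),
    seed: int = 0,
    samples: int | None = None,
) -> ConditionResult:
    """Stabilize one (clone x treatment) condition and read the phenotypes."""
    treatment = _treatment_tuple(treatment)
    clone_fixed = {p.variable for p in clone.perturbations}
    for t in treatment:
        model.variable(t)  # raises for unknown nodes
        if t in clone_fixed:
            raise QNModelError(
                f"cannot treat {t!r}: it is already fixed by clone {clone.name!r}"
            )
    perturbs = list(clone.perturbations) + [Perturbation(t, "inhibit") for t in treatment]
    kwargs = {} if samples is None else {"samples": samples}
    _, summaries, _ = stabilize(model, perturbs, seed=seed, **kwargs)
    return ConditionResult(
        clone=clone.name,
        treatment=treatment,
        proliferation=summaries[PROLIFERATION],
        apoptosis=summaries[APOPTOSIS],
    )


def model_hash(model: QNModel) -> str:
    return hashlib.sha256(serialize_model_text(model).encode()).hexdigest()[:16]


def druggable_targets(model: QNModel) -> list:
    return [v.name for v in model.variables if v.druggable]


def run_screen(
    model: QNModel,
    clones,
    targets=None,
    seed: int = 0,
    include_baseline: bool = True,
    samples: int | None = None,
) -> ScreenTable:
    """Complete mono + pairwise inhibition table over the given clones.

    ``targets`` defaults to the druggable-annotated nodes; pass all node
    names to screen every node.  Pairs are unordered; rerunning with the
    same seed reproduces the table exactly.
    """
    if targets is None:
        targets = druggable_targets(model)
    targets = sorted(targets)
    if isinstance(clones, dict):
        clones = list(clones.values())
    treatments = []
    if include_baseline:
        treatments.append(())
    treatments += [(t,) for t in targets]
    treatments += [tuple(sorted(p)) for p in itertools.combinations(targets, 2)]

    rows = []
    for clone in clones:
        for treatment in treatments:
            res = evaluate_condition(model, clone, treatment, seed=seed, samples=samples)
            rows.append(
                {
                    "clone": res.clone,
                    "treatment": "+".join(res.treatment),
                    "n_inhibitors": len(res.treatment),
                    "proliferation_min": res.proliferation.min,
                    "proliferation_max": res.proliferation.max,
                    "proliferation_mid": res.proliferation.midpoint,
                    "apoptosis_min": res.apoptosis.min,
                    "apoptosis_max": res.apoptosis.max,
                    "apoptosis_mid": res.apoptosis.midpoint,
                    "outcome": res.outcome,
                }
            )
    data = pd.DataFrame(rows)
    provenance = {
        "model": model.name,
        "model_hash": model_hash(model),
        "seed": seed,
        "targets": targets,
        "clones": [c.name for c in clones],
    }
    return ScreenTable(data=data, provenance=provenance)


def healthy_toxicity_filter(table: ScreenTable, threshold: float = 3.0) -> dict:
    """Treatment -> True when healthy-cell apoptosis midpoint exceeds the
    threshold (strictly).  Raises if the table has no healthy rows."""
    healthy = table.data[table.data["clone"] == "healthy"]
    if healthy.empty:
        raise QNModelError("screen table contains no healthy-clone rows")
    return {
        row["treatment"]: bool(row["apoptosis_mid"] > threshold)
        for _, row in healthy.iterrows()
        if row["n_inhibitors"] > 0
    }


def effective_monotherapies(
    table: ScreenTable,
    metric: str = "apoptosis",
    eps: float = 0.0,
    clones=MIXED_TUMOR_CLONES,
) -> list:
    """Targets whose monotherapy moves the metric in the beneficial
    direction (apoptosis up, proliferation down) by more than ``eps`` in at
    least one of the given tumor clones."""
    sign = 1.0 if metric == "apoptosis" else -1.0
    out = []
    monos = sorted(
        set(
            t
            for t in table.data.loc[table.data["n_inhibitors"] == 1, "treatment"]
        )
    )
    for target in monos:
        for clone in clones:
            base = table.midpoint(clone, (), metric)
            treated = table.midpoint(clone, (target,), metric)
            if sign * (treated - base) > eps:
                out.append(target)
                break
    return out


def delta_matrix(
    table: ScreenTable,
    metric: str = "apoptosis",
    first=None,
    toxicity_threshold: float = 3.0,
    drop_phd2_vhl: bool = False,
    clones=MIXED_TUMOR_CLONES,
    eps: float = 0.0,
) -> DeltaMatrix:
    """Change matrices for adding a second inhibitor to a monotherapy.

    ``values[a][b]`` is the mean over the tumor clones of
    ``metric(pair {a, b}) - metric(mono a)``.  Rows are restricted to
    effective monotherapies (unless ``first`` overrides); cells are masked
    for same-node "pairs", for treatments toxic to healthy cells, and
    (optionally, presentation-layer only) for the PHD2/VHL rows/columns.
    """
    if first is None:
        first = effective_monotherapies(table, metric=metric, eps=eps, clones=clones)
    first = sorted(first)
    targets = sorted(
        set(table.data.loc[table.data["n_inhibitors"] == 1, "treatment"])
    )
    toxic = healthy_toxicity_filter(table, threshold=toxicity_threshold)

    values = pd.DataFrame(index=first, columns=targets, dtype=float)
    mask = pd.DataFrame("", index=first, columns=targets)
    for a in first:
        for b in targets:
            if a == b:
                mask.loc[a, b] = "same_node"
                continue
            pair_key = "+".join(sorted((a, b)))
            if toxic.get(pair_key, False):
                mask.loc[a, b] = "healthy_toxicity"
            if drop_phd2_vhl and ({a, b} & {"PHD2", "VHL"}) and {a, b} != {"PHD2", "VHL"}:
                mask.loc[a, b] = (mask.loc[a, b] + ";phd2_vhl").lstrip(";")
            deltas = [
                table.midpoint(c, (a, b), metric) - table.midpoint(c, (a,), metric)
                for c in clones
            ]
            values.loc[a, b] = float(np.mean(deltas))
    return DeltaMatrix(metric=metric, values=values, mask=mask, clones=tuple(clones))


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def export_table(table: ScreenTable, path) -> None:
    """Tidy CSV plus a JSON provenance sidecar (deterministic content)."""
    table.data.to_csv(path, index=False)
    with open(str(path) + ".provenance.json", "w", encoding="utf-8") as fh:
        json.dump(table.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")


def export_matrix(
    matrix: DeltaMatrix,
    csv_path=None,
    figure_path=None,
    model: QNModel | None = None,
) -> None:
    """CSV (masked cells empty, with a reason table alongside) and an
    optional heatmap with pathway-ordered axes and a pathway color strip."""
    if csv_path is not None:
        out = matrix.masked_values()
        out.to_csv(csv_path)
        matrix.mask.to_csv(str(csv_path) + ".mask.csv")
    if figure_path is not None:
        _plot_matrix(matrix, figure_path, model)


def _pathway_order(names, model: QNModel | None):
    if model is None:
        return sorted(names)
    def key(n):
        v = model.by_name.get(n)
        return ((v.pathway if v else ""), n)
    return sorted(names, key=key)


def _plot_matrix(matrix: DeltaMatrix, path, model: QNModel | None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = _pathway_order(list(matrix.values.index), model)
    cols = _pathway_order(list(matrix.values.columns), model)
    data = matrix.masked_values().loc[rows, cols]

    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(cols), 1 + 0.5 * len(rows)))
    im = ax.imshow(data.to_numpy(dtype=float), cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=90)
    ax.set_yticks(range(len(rows)), rows)
    ax.set_xlabel("added inhibitor")
    ax.set_ylabel("first inhibitor (effective monotherapy)")
    ax.set_title(f"mean change in {matrix.metric} across {', '.join(matrix.clones)}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if model is not None:
        pathways = sorted({v.pathway for v in model.variables if v.pathway})
        cmap = plt.get_cmap("tab10")
        colors = {p: cmap(i % 10) for i, p in enumerate(pathways)}
        for j, c in enumerate(cols):
            v = model.by_name.get(c)
            if v and v.pathway:
                ax.add_patch(
                    plt.Rectangle((j - 0.5, len(rows) - 0.5), 1, 0.3,
                                  color=colors[v.pathway], clip_on=False)
                )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
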