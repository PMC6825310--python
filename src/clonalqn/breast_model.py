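"""The curated Myc/Ras/p53/Wnt/HIF breast-tumor network.

A qualitative network of the oncogenic signaling cross talk in Wnt-driven,
estrogen-receptor-negative mammary tumors carrying heterogeneous Myc
activity.  The network is a literature-constrained reconstruction: each
edge carries a mechanism comment, and the model's acceptance surface is a
suite of qualitative claims (orderings of phenotype readouts across clone
configurations) rather than edge-list identity.

Two variants are built:

* ``in_vitro`` — includes HER2 alongside EGFR (cell-line context) and has
  no angiogenesis phenotype;
* ``in_vivo``  — drops HER2 (the tumors are not HER2 driven) and adds an
  angiogenesis phenotype node fed by VEGF and by the Myc-instructed
  angiogenic program.

Clone configurations encode cell populations as node fixings only:

* ``healthy``        — unmutated tissue, baseline microenvironment;
* ``myc_low``        — Wnt-driven tumor cell in a pure Myc-low tumor:
                       strong autocrine/paracrine Wnt, but an indolent,
                       hypovascular and therefore hypoxic lesion;
* ``myc_low_mixed``  — the same cell inside a biclonal tumor whose Myc-high
                       neighbors instruct an angiogenic, normoxic stroma;
* ``myc_high_pure``  — Myc forced to maximum; its own Wnt1 is suppressed by
                       the Myc negative feedback and, with only Myc-high
                       neighbors, the paracrine Wnt source is lowered too;
* ``myc_high_mixed`` — Myc at maximum plus a raised paracrine Wnt source
                       supplied by Myc-low neighbors (the mutualism circuit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .bma_io import load_model, parse_formula
from .qn_core import Perturbation, QNModel, RelationshipDef, VariableDef

__all__ = [
    "ModelVariant",
    "CloneConfig",
    "build_breast_model",
    "clone_configs",
    "load_builtin_model",
    "load_clone_configs",
    "save_clone_configs",
    "clone_configs_to_doc",
    "expectation_table",
    "validate_expectations",
    "PHENOTYPES",
    "DRUG_EXAMPLES",
]

PHENOTYPES = ("Proliferation", "Apoptosis", "Angiogenesis")

#: Static druggability annotation (a snapshot of drug-gene interaction
#: knowledge; never a live query).  Example agents per druggable node.
DRUG_EXAMPLES = {
    "EGFR": "erlotinib, lapatinib",
    "MEK": "PD0325901, trametinib",
    "COX2": "celecoxib",
    "Wnt1": "porcupine inhibitors (LGK974)",
    "GSK3b": "lithium, tideglusib",
    "PHD2": "prolyl-hydroxylase inhibitors (roxadustat)",
    "VHL": "experimental E3-ligase blockers",
    "VEGF": "bevacizumab",
    "HER2": "trastuzumab (in-vitro variant only)",
}


@dataclass(frozen=True)
class ModelVariant:
    name: str  # "in_vitro" | "in_vivo"

    def __post_init__(self):
        if self.name not in ("in_vitro", "in_vivo"):
            raise ValueError(f"unknown variant {self.name!r}")


@dataclass(frozen=True)
class CloneConfig:
    """A named bundle of node fixings representing one cell population."""

    name: str
    perturbations: tuple
    description: str = ""

    def perturbation_list(self):
        return list(self.perturbations)


class _Builder:
    def __init__(self, name):
        self.vars = []
        self.rels = []
        self._id = 0
        self.name = name

    def var(self, name, pathway, formula=None, constitutive=None, druggable=False):
        self._id += 1
        self.vars.append(
            dict(
                id=self._id,
                name=name,
                pathway=pathway,
                formula=formula,
                constitutive=constitutive,
                druggable=druggable,
            )
        )
        return name

    def edge(self, src, dst, sign):
        self.rels.append((src, dst, sign))

    def activate(self, src, dst):
        self.edge(src, dst, "activator")

    def inhibit(self, src, dst):
        self.edge(src, dst, "inhibitor")

    def build(self):
        scope = {v["name"] for v in self.vars}
        variables = [
            VariableDef(
                id=v["id"],
                name=v["name"],
                range_min=0,
                range_max=4,
                formula=None if v["formula"] is None else parse_formula(v["formula"], scope),
                constitutive=v["constitutive"],
                pathway=v["pathway"],
                druggable=v["druggable"],
            )
            for v in self.vars
        ]
        ids = {v["name"]: v["id"] for v in self.vars}
        relationships = [
            RelationshipDef(ids[s], ids[d], sign) for s, d, sign in self.rels
        ]
        return QNModel(variables, relationships, name=self.name)


def build_breast_model(variant="in_vivo") -> QNModel:
    """Construct one variant of the breast-tumor network.

    All nodes share the activity range 0..4.  Target functions are the
    default ``avg(activators) - avg(inhibitors)`` unless a mechanism
    demands otherwise; every custom formula carries a justification
    comment.
    """
    if isinstance(variant, ModelVariant):
        variant = variant.name
    ModelVariant(variant)  # validates
    in_vivo = variant == "in_vivo"
    b = _Builder(f"breast_{variant}")

    # ---- microenvironment ------------------------------------------------
    # External conditions; clone configurations fix these nodes.
    b.var("EGF", "microenvironment", constitutive=2)          # ambient growth factor tone
    b.var("WntDrive", "microenvironment", constitutive=2)     # transcriptional drive of the cell's own Wnt1 gene (physiological niche level; the oncogenic transgene forces it to 4)
    b.var("WntEnv", "microenvironment", constitutive=2)       # paracrine Wnt available from neighboring cells
    b.var("Hypoxia", "microenvironment", constitutive=1)      # tissue oxygenation deficit
    b.var("Inflammation", "microenvironment", constitutive=2) # inflammatory tone driving COX2
    b.var("Stress", "microenvironment", constitutive=0)       # oncogenic/replicative stress of the transformed background (0 in normal tissue)

    # ---- Wnt module --------------------------------------------------------
    # The cell's own secreted Wnt1: driven by WntDrive, repressed by Myc
    # (high Myc shuts down Wnt1 expression - the negative feedback that
    # starves pure Myc-high tumors of their survival signal).
    b.var("Wnt1", "Wnt", druggable=True)
    b.activate("WntDrive", "Wnt1")
    b.inhibit("Myc", "Wnt1")
    # Receptor engagement integrates autocrine and paracrine ligand.
    b.var("Frizzled", "Wnt")
    b.activate("Wnt1", "Frizzled")
    b.activate("WntEnv", "Frizzled")
    # Canonical cascade: receptor signal restrains GSK3beta, stabilizing
    # beta-catenin (constitutively synthesized, constitutively degraded).
    b.var("GSK3b", "Wnt", constitutive=4, druggable=True)
    b.inhibit("Frizzled", "GSK3b")
    b.var("BetaCatenin", "Wnt", constitutive=4)
    b.inhibit("GSK3b", "BetaCatenin")

    # ---- EGFR / Ras / MAPK -------------------------------------------------
    b.var("EGFR", "EGFR/HER2", druggable=True)
    b.activate("EGF", "EGFR")
    if not in_vivo:
        # HER2 heterodimerization amplifies EGFR signaling in the cell-line
        # context; the tumors themselves are not HER2 driven.
        b.var("HER2", "EGFR/HER2", constitutive=2, druggable=True)
        b.activate("HER2", "EGFR")
    # Tonic RTK input other than EGFR (e.g. IGF1R) keeps Ras from being a
    # pure EGFR relay.
    b.var("IGF1R", "Ras/MAPK", constitutive=2)
    b.var("Ras", "Ras/MAPK")
    b.activate("EGFR", "Ras")
    b.activate("IGF1R", "Ras")
    # RAF/MEK excluded from the druggable set: RAF inhibitors paradoxically
    # activate MAPK signaling in Ras-driven cells, so only MEK is treated
    # as the actionable kinase of the cascade in this snapshot.
    b.var("Raf", "Ras/MAPK")
    b.activate("Ras", "Raf")
    b.var("MEK", "Ras/MAPK", druggable=True)
    b.activate("Raf", "MEK")
    b.var("ERK", "Ras/MAPK")
    b.activate("MEK", "ERK")

    # ---- Myc ---------------------------------------------------------------
    # Myc integrates mitogenic ERK signaling with canonical Wnt signaling.
    b.var("Myc", "Ras/MAPK")
    b.activate("ERK", "Myc")
    b.activate("BetaCatenin", "Myc")

    # ---- p53 / apoptosis machinery -----------------------------------------
    # ARF is engaged only by supraphysiological Myc (2*Myc-4 is zero up to
    # the physiological mid-range), and active Wnt signaling quenches the
    # ARF->p53 induction (receptor-proximal signal used, as the quenching
    # mechanism is upstream of beta-catenin target genes).
    b.var("p19ARF", "p53", formula="2*var(Myc) - 4 - var(Frizzled)")
    b.edge("Myc", "p19ARF", "activator")
    b.edge("Frizzled", "p19ARF", "inhibitor")
    # Mdm2 constitutively degrades p53; ARF sequesters Mdm2, and hypoxic
    # stress also restrains it, so p53 integrates oncogenic and hypoxic
    # stress: p53 = avg(ARF, HIF1a).
    b.var("Mdm2", "p53", constitutive=4)
    b.inhibit("p19ARF", "Mdm2")
    b.inhibit("HIF1a", "Mdm2")
    b.var("p53", "p53", constitutive=4)
    b.inhibit("Mdm2", "p53")
    b.var("PUMA", "p53")
    b.activate("p53", "PUMA")
    b.var("NOXA", "p53")
    b.activate("p53", "NOXA")
    # p21 routes p53 to cell-cycle arrest; Myc-Miz1 represses p21, which is
    # why Myc-high cells are resistant to arrest but not to apoptosis.
    b.var("p21", "p53")
    b.activate("p53", "p21")
    b.inhibit("Myc", "p21")

    # ---- COX2 / prostaglandin axis -----------------------------------------
    b.var("COX2", "inflammation", druggable=True)
    b.activate("Inflammation", "COX2")
    b.activate("ERK", "COX2")
    b.var("PGE2", "inflammation")
    b.activate("COX2", "PGE2")

    # ---- hypoxia / HIF -----------------------------------------------------
    # PHD2 and VHL act sequentially in HIF1a degradation (hydroxylation,
    # then ubiquitination); both are modeled at a fixed normoxic capacity.
    b.var("PHD2", "HIF/hypoxia", constitutive=3, druggable=True)
    b.var("VHL", "HIF/hypoxia", constitutive=3, druggable=True)
    # HIF1a accumulates when hypoxia outpaces the degradation machinery;
    # the 2x gain makes deep hypoxia dominate the normoxic degradation
    # capacity (nuclear HIF1a marks only the strongly hypoxic lesions).
    b.var("HIF1a", "HIF/hypoxia", formula="2*var(Hypoxia) - avg(var(PHD2),var(VHL))")
    b.edge("Hypoxia", "HIF1a", "activator")
    b.edge("PHD2", "HIF1a", "inhibitor")
    b.edge("VHL", "HIF1a", "inhibitor")
    # Modeling device for the degradation-arm imbalance: blocking exactly
    # one arm of the PHD2->VHL degradation route triggers a BNIP3-type
    # mitochondrial death signal (aberrant accumulation of partially
    # processed HIF species), while blocking both arms yields a coherent
    # pseudohypoxic state without that signal.
    b.var("Bnip3", "HIF/hypoxia",
          formula="2*max(var(PHD2) - var(VHL), var(VHL) - var(PHD2)) - 2")
    b.edge("PHD2", "Bnip3", "activator")
    b.edge("VHL", "Bnip3", "inhibitor")

    # ---- integrators and phenotypes ----------------------------------------
    # Antiapoptotic tone: ERK survival signaling and prostaglandin
    # signaling.  The canonical Wnt survival signal is not pooled here; it
    # acts by quenching the ARF->p53 apoptotic effector (see p19ARF above),
    # which is the mechanism by which paracrine Wnt rescues Myc-high cells.
    b.var("Survival", "phenotype-input")
    b.activate("ERK", "Survival")
    b.activate("PGE2", "Survival")
    # Cell-cycle drive integrates Myc, ERK and Wnt; arrested by p21 and by
    # hypoxic HIF signaling.
    b.var("CyclinD", "phenotype-input")
    b.activate("Myc", "CyclinD")
    b.activate("ERK", "CyclinD")
    b.activate("BetaCatenin", "CyclinD")
    b.inhibit("p21", "CyclinD")
    b.inhibit("HIF1a", "CyclinD")
    b.var("VEGF", "HIF/hypoxia", druggable=True)
    b.activate("HIF1a", "VEGF")
    b.activate("Myc", "VEGF")

    b.var("Proliferation", "phenotype")
    b.activate("CyclinD", "Proliferation")
    # Apoptosis: the p53-driven BH3 program must overcome the antiapoptotic
    # buffer; the tumor's constitutive stress load adds to the BH3 side.
    # The BNIP3 arm acts on mitochondria independently of that buffer,
    # hence the max().
    b.var(
        "Apoptosis",
        "phenotype",
        formula="max(avg(var(PUMA),var(NOXA)) + var(Stress) - var(Survival), var(Bnip3))",
    )
    b.edge("PUMA", "Apoptosis", "activator")
    b.edge("NOXA", "Apoptosis", "activator")
    b.edge("Stress", "Apoptosis", "activator")
    b.edge("Survival", "Apoptosis", "inhibitor")
    b.edge("Bnip3", "Apoptosis", "activator")
    if in_vivo:
        # The angiogenic switch: VEGF release plus the Myc-instructed
        # stromal program.
        b.var("Angiogenesis", "phenotype")
        b.activate("VEGF", "Angiogenesis")
        b.activate("Myc", "Angiogenesis")

    if not in_vivo:
        # keep VEGF on a path to a phenotype in the variant without an
        # angiogenesis node: autocrine VEGFR survival signaling
        b.activate("VEGF", "Survival")

    return b.build()


def clone_configs() -> dict:
    """The five clone configurations (node fixings only)."""

    def force(var, level):
        return Perturbation(var, "force", level)

    cfgs = [
        CloneConfig(
            "healthy",
            (),
            "unmutated cell, baseline microenvironment; no oncogenic fixings",
        ),
        CloneConfig(
            "myc_low",
            (
                force("WntDrive", 4),  # oncogenic Wnt transgene
                force("WntEnv", 4),    # neighbors secrete Wnt too
                force("Hypoxia", 3),   # indolent hypovascular lesion
                force("Stress", 1),    # transformed background
            ),
            "Myc-low tumor cell in a pure Myc-low tumor (hypoxic stroma)",
        ),
        CloneConfig(
            "myc_low_mixed",
            (
                force("WntDrive", 4),
                force("WntEnv", 4),
                force("Hypoxia", 1),   # Myc-high neighbors instruct angiogenesis
                force("Stress", 1),
            ),
            "Myc-low tumor cell inside a biclonal tumor (normoxic stroma)",
        ),
        CloneConfig(
            "myc_high_pure",
            (
                force("Myc", 4),       # deregulated Myc at maximum
                force("WntDrive", 4),
                force("WntEnv", 0),    # all neighbors also suppress Wnt1: lowered paracrine source
                force("Hypoxia", 1),   # angiogenic, normoxic stroma
                force("Stress", 1),
            ),
            "Myc-high tumor cell in a pure Myc-high tumor (Wnt-starved)",
        ),
        CloneConfig(
            "myc_high_mixed",
            (
                force("Myc", 4),
                force("WntDrive", 4),
                force("WntEnv", 4),    # raised paracrine Wnt from Myc-low neighbors
                force("Hypoxia", 1),
                force("Stress", 1),
            ),
            "Myc-high tumor cell rescued by paracrine Wnt from Myc-low neighbors",
        ),
    ]
    return {c.name: c for c in cfgs}


# --------------------------------------------------------------------------
# Committed data files
# --------------------------------------------------------------------------

def load_builtin_model(variant="in_vivo") -> QNModel:
    """Load the committed JSON model file for a variant.

    The committed files are exported from :func:`build_breast_model`; a
    test keeps them in sync with the in-code builder.
    """
    if isinstance(variant, ModelVariant):
        variant = variant.name
    ModelVariant(variant)
    path = resources.files("clonalqn").joinpath(f"data/breast_{variant}.json")
    with resources.as_file(path) as p:
        return load_model(p)


def clone_configs_to_doc(configs=None) -> dict:
    configs = configs or clone_configs()
    return {
        "clones": [
            {
                "name": c.name,
                "description": c.description,
                "perturbations": [
                    {"variable": p.variable, "mode": p.mode, "level": p.level}
                    for p in c.perturbations
                ],
            }
            for c in configs.values()
        ]
    }


def save_clone_configs(path, configs=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(clone_configs_to_doc(configs), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_clone_configs(path=None) -> dict:
    """Read clone configurations from a JSON file (default: the committed
    one).  Schema: ``{"clones": [{"name", "description", "perturbations":
    [{"variable", "mode", "level"}]}]}``."""
    if path is None:
        res = resources.files("clonalqn").joinpath("data/clones.json")
        with resources.as_file(res) as p:
            return load_clone_configs(p)
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    out = {}
    for rec in doc["clones"]:
        perturbs = tuple(
            Perturbation(p["variable"], p.get("mode", "force"), p.get("level"))
            for p in rec["perturbations"]
        )
        out[rec["name"]] = CloneConfig(rec["name"], perturbs, rec.get("description", ""))
    return out


# --------------------------------------------------------------------------
# Qualitative expectation suite
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Expectation:
    claim: str
    kind: str          # "order" | "threshold"
    node: str
    left: object       # clone name, or (clone, treatment) tuple
    right: object      # clone/condition for "order"; numeric bound for "threshold"
    relation: str      # ">", "<", ">=", "<="
    rationale: str


def expectation_table() -> list:
    """Qualitative claims the curated model must reproduce.

    ``left``/``right`` entries are ``(clone, treatment)`` pairs, where the
    treatment is a tuple of inhibited node names (empty = untreated).
    """
    E = Expectation
    u = ()  # untreated
    return [
        E(
            "myc_high_apoptosis",
            "order", "Apoptosis",
            ("myc_high_pure", u), ("myc_low", u), ">",
            "deregulated Myc dramatically raises tumor-cell apoptosis",
        ),
        E(
            "wnt_rescue_of_apoptosis",
            "order", "Apoptosis",
            ("myc_high_mixed", u), ("myc_high_pure", u), "<",
            "paracrine Wnt from Myc-low neighbors suppresses Myc-driven apoptosis",
        ),
        E(
            "hif_fall_on_myc_activation",
            "order", "HIF1a",
            ("myc_low", u), ("myc_high_pure", u), ">",
            "the angiogenic switch of Myc-high tumors abolishes nuclear HIF1a",
        ),
        E(
            "arf_quenching_by_wnt",
            "order", "p19ARF",
            ("myc_high_mixed", u), ("myc_high_pure", u), "<",
            "Wnt signaling quenches the ARF->p53 apoptotic effector",
        ),
        E(
            "wnt_signal_low_in_pure_myc_high",
            "threshold", "BetaCatenin",
            ("myc_high_pure", u), 1.0, "<=",
            "pure Myc-high tumors lose nuclear beta-catenin",
        ),
        E(
            "p53_engaged_in_pure_myc_high",
            "threshold", "p53",
            ("myc_high_pure", u), 2.0, ">=",
            "p53 accumulates after Myc activation",
        ),
        E(
            "proliferation_maintained_high_pure",
            "order", "Proliferation",
            ("myc_high_pure", u), ("myc_low", u), ">=",
            "Myc-high cells are resistant to cell-cycle arrest",
        ),
        E(
            "proliferation_maintained_high_mixed",
            "order", "Proliferation",
            ("myc_high_mixed", u), ("myc_low", u), ">=",
            "mixed tumors keep the proliferative advantage of Myc-high cells",
        ),
        E(
            "healthy_baseline_viable",
            "threshold", "Apoptosis",
            ("healthy", u), 3.0, "<=",
            "untreated healthy cells stay below the toxicity bound",
        ),
        E(
            "mek_more_apoptotic_in_myc_high",
            "order", "Apoptosis",
            ("myc_high_mixed", ("MEK",)), ("myc_low_mixed", ("MEK",)), ">",
            "MEK inhibition blocks antiapoptotic signaling, hitting the "
            "apoptosis-primed Myc-high clone hardest",
        ),
        E(
            "combo_beats_mek_in_myc_low",
            "order", "Apoptosis",
            ("myc_low_mixed", ("COX2", "MEK")), ("myc_low_mixed", ("MEK",)), ">",
            "adding COX2 inhibition raises proapoptotic pressure beyond MEK alone",
        ),
        E(
            "combo_beats_cox2_in_myc_low",
            "order", "Apoptosis",
            ("myc_low_mixed", ("COX2", "MEK")), ("myc_low_mixed", ("COX2",)), ">",
            "the combination outperforms COX2 monotherapy in the Myc-low clone",
        ),
    ]


def validate_expectations(model: QNModel, clones=None, seed: int = 0) -> pd.DataFrame:
    """Evaluate every qualitative claim; returns a pass/fail report.

    Claims compare NodeSummary midpoints between (clone, treatment)
    conditions.
    """
    from .qn_core import stabilize

    clones = clones or clone_configs()
    cache: dict = {}

    def midpoint(node, condition):
        clone_name, treatment = condition
        key = (clone_name, tuple(sorted(treatment)))
        if key not in cache:
            perturbs = clones[clone_name].perturbation_list() + [
                Perturbation(t, "inhibit") for t in treatment
            ]
            _, summaries, _ = stabilize(model, perturbs, seed=seed)
            cache[key] = summaries
        return cache[key][node].midpoint

    ops = {
        ">": lambda a, b: a > b,
        "<": lambda a, b: a < b,
        ">=": lambda a, b: a >= b,
        "<=": lambda a, b: a <= b,
    }
    rows = []
    for e in expectation_table():
        left = midpoint(e.node, e.left)
        if e.kind == "order":
            right = midpoint(e.node, e.right)
        else:
            right = float(e.right)
        rows.append(
            {
                "claim": e.claim,
                "node": e.node,
                "left": left,
                "relation": e.relation,
                "right": right,
                "passed": ops[e.relation](left, right),
                "rationale": e.rationale,
            }
        )
    return pd.DataFrame(rows)
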