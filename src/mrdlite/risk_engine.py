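"""Clinical classifiers and configurable risk-stratification trees.

Implements the protocol's categorical classifiers (CNS status, marrow
morphologic response, prednisone response) and a small YAML-driven
decision-tree engine that assigns a risk group (VLR < LR < IR < HR) under
two workflows: ORIGINAL (clinical features only) and UPDATED (re-classified
by the day-15 MRD category). Every traversal produces a full decision
trace for auditability.

Boundary conventions (fixed and documented):
  * CNS3 criteria take precedence over CNS2.
  * Marrow M2 is the half-open interval [5, 25)% so that fractional values
    between the printed "5% to 24%" and ">= 25%" rules are covered.
  * Prednisone poor response is >= 1000 blasts/mm^3 at day 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

from .config import load_risk_tree_config

__all__ = [
    "RISK_GROUPS",
    "CsfFinding",
    "PatientRecord",
    "RiskAssignment",
    "MissingFeatureError",
    "TreeConfigError",
    "classify_cns",
    "classify_marrow",
    "classify_prednisone_response",
    "assign_risk",
    "risk_order",
]

#: ordinal risk scale, least to most intensive therapy
RISK_GROUPS = ("VLR", "LR", "IR", "HR")

MRD_CATEGORIES = ("NEG_LT_0.01", "POS_0.01_0.1", "POS_0.1_10", "POS_GT_10")


class MissingFeatureError(KeyError):
    """A feature required by the tree is absent from the patient record."""

    def __init__(self, feature: str):
        self.feature = feature
        super().__init__(f"patient record is missing feature required by the tree: {feature}")


class TreeConfigError(ValueError):
    """Malformed risk-tree configuration."""


@dataclass(frozen=True)
class CsfFinding:
    """Cerebrospinal-fluid findings at diagnosis."""

    wbc_per_mm3: float
    blasts_present: bool
    rbc_per_mm3: float = 0.0
    hours_after_therapy_start: float | None = None
    cranial_nerve_palsy: bool = False
    cerebral_mass: bool = False

    def __post_init__(self) -> None:
        if self.wbc_per_mm3 < 0 or self.rbc_per_mm3 < 0:
            raise ValueError("CSF cell counts must be non-negative")
        if self.hours_after_therapy_start is not None and self.hours_after_therapy_start < 0:
            raise ValueError("hours_after_therapy_start must be non-negative")


@dataclass(frozen=True)
class PatientRecord:
    """Clinical features feeding the risk decision trees.

    ``day15_mrd`` is any object exposing ``category``/``reportable``
    attributes (an MRDResult); it may be absent for the ORIGINAL workflow.
    """

    patient_id: str
    age_years: float
    wbc_per_ul: float
    lineage: str = "B_PRECURSOR"
    csf: CsfFinding | None = None
    day8_peripheral_blasts_per_mm3: float | None = None
    day15_mrd: Any | None = None
    day33_marrow_blast_pct: float | None = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age must be non-negative")
        if self.wbc_per_ul < 0:
            raise ValueError("WBC must be non-negative")
        if self.lineage not in ("B_PRECURSOR", "T", "OTHER"):
            raise ValueError(f"unknown lineage {self.lineage!r}")


@dataclass(frozen=True)
class RiskAssignment:
    group: str
    workflow: str
    trace: tuple[tuple[str, Any, Any], ...]  # (rule id, input value, outcome)

    def __post_init__(self) -> None:
        if self.group not in RISK_GROUPS:
            raise ValueError(f"unknown risk group {self.group!r}")
        if not self.trace:
            raise ValueError("trace must be non-empty")


def risk_order(group: str) -> int:
    """Ordinal position of a risk group (VLR=0 ... HR=3)."""
    return RISK_GROUPS.index(group)


# --------------------------------------------------------------------------
# categorical classifiers

def classify_cns(csf: CsfFinding) -> str:
    """CNS involvement category.

    CNS3: CSF > 5 cells/mm^3 with blasts, or cranial nerve palsy, or a
    cerebral mass. CNS2: CSF <= 5 cells/mm^3 with blasts, or a traumatic
    tap (> 10 erythrocytes/mm^3), or a tap performed > 72 h after the
    start of therapy. CNS1 otherwise. CNS3 criteria are evaluated first.
    """
    if (csf.wbc_per_mm3 > 5 and csf.blasts_present) or csf.cranial_nerve_palsy or csf.cerebral_mass:
        return "CNS3"
    traumatic = csf.rbc_per_mm3 > 10
    late = csf.hours_after_therapy_start is not None and csf.hours_after_therapy_start > 72
    if (csf.blasts_present and csf.wbc_per_mm3 <= 5) or traumatic or late:
        return "CNS2"
    return "CNS1"


def classify_marrow(blast_pct: float) -> str:
    """Morphologic marrow response: M1 < 5%, M2 in [5, 25)%, M3 >= 25%."""
    if not 0.0 <= blast_pct <= 100.0:
        raise ValueError(f"marrow blast percentage {blast_pct} outside [0, 100]")
    if blast_pct < 5.0:
        return "M1"
    if blast_pct < 25.0:
        return "M2"
    return "M3"


def classify_prednisone_response(day8_blasts_per_mm3: float) -> str:
    """POOR iff >= 1000 peripheral blasts/mm^3 after seven days of prednisone."""
    if day8_blasts_per_mm3 < 0:
        raise ValueError("blast count must be non-negative")
    return "POOR" if day8_blasts_per_mm3 >= 1000.0 else "GOOD"


# --------------------------------------------------------------------------
# tree engine

_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
}


def _feature_value(record: PatientRecord, feature: str) -> Any:
    """Resolve a (possibly derived) feature from the record; raise
    MissingFeatureError when the underlying datum is absent."""
    if feature == "age_years":
        return record.age_years
    if feature == "wbc_per_ul":
        return record.wbc_per_ul
    if feature == "lineage":
        return record.lineage
    if feature == "cns_class":
        if record.csf is None:
            raise MissingFeatureError("csf")
        return classify_cns(record.csf)
    if feature == "prednisone_response":
        if record.day8_peripheral_blasts_per_mm3 is None:
            raise MissingFeatureError("day8_peripheral_blasts_per_mm3")
        return classify_prednisone_response(record.day8_peripheral_blasts_per_mm3)
    if feature == "day33_marrow_blast_pct":
        if record.day33_marrow_blast_pct is None:
            raise MissingFeatureError("day33_marrow_blast_pct")
        return record.day33_marrow_blast_pct
    if feature == "day33_marrow_class":
        if record.day33_marrow_blast_pct is None:
            raise MissingFeatureError("day33_marrow_blast_pct")
        return classify_marrow(record.day33_marrow_blast_pct)
    if feature == "mrd_category":
        if record.day15_mrd is None:
            raise MissingFeatureError("day15_mrd")
        return record.day15_mrd.category
    if feature == "mrd_reportable":
        if record.day15_mrd is None:
            raise MissingFeatureError("day15_mrd")
        return bool(record.day15_mrd.reportable)
    raise TreeConfigError(f"tree references unknown feature {feature!r}")


def _validate_node(node: Any, seen_ids: set[str], workflows: set[str]) -> None:
    if not isinstance(node, dict):
        raise TreeConfigError(f"tree node must be a mapping, got {type(node).__name__}")
    if "risk" in node:
        if node["risk"] not in RISK_GROUPS:
            raise TreeConfigError(f"leaf risk {node['risk']!r} not in {RISK_GROUPS}")
        return
    if "defer" in node:
        if node["defer"] not in workflows:
            raise TreeConfigError(f"defer target {node['defer']!r} is not a workflow")
        return
    for key in ("id", "feature", "op", "value", "then", "else"):
        if key not in node:
            raise TreeConfigError(f"decision node missing field {key!r}: {node}")
    if node["id"] in seen_ids:
        raise TreeConfigError(f"duplicate rule id {node['id']!r}")
    seen_ids.add(node["id"])
    if node["op"] not in _OPS:
        raise TreeConfigError(f"unknown comparator {node['op']!r} in rule {node['id']}")
    _validate_node(node["then"], seen_ids, workflows)
    _validate_node(node["else"], seen_ids, workflows)


def validate_tree(tree: dict[str, Any]) -> dict[str, Any]:
    """Validate a workflows config ({'workflows': {NAME: root-node}})."""
    if "workflows" not in tree or not isinstance(tree["workflows"], dict):
        raise TreeConfigError("tree config must contain a 'workflows' mapping")
    names = set(tree["workflows"])
    for name, root in tree["workflows"].items():
        _validate_node(root, set(), names)
    return tree


def _traverse(record: PatientRecord, node: dict[str, Any],
              workflows: dict[str, Any],
              trace: list[tuple[str, Any, Any]],
              depth: int = 0) -> str:
    if depth > 100:
        raise TreeConfigError("tree traversal exceeded depth limit (cycle?)")
    if "risk" in node:
        return node["risk"]
    if "defer" in node:
        trace.append((f"defer:{node['defer']}", None, node["defer"]))
        return _traverse(record, workflows[node["defer"]], workflows, trace, depth + 1)
    value = _feature_value(record, node["feature"])
    outcome = bool(_OPS[node["op"]](value, node["value"]))
    trace.append((node["id"], value, outcome))
    nxt = node["then"] if outcome else node["else"]
    return _traverse(record, nxt, workflows, trace, depth + 1)


def assign_risk(record: PatientRecord,
                tree: dict[str, Any] | None = None,
                workflow: str = "UPDATED") -> RiskAssignment:
    """Deterministically traverse the configured tree for one workflow.

    The UPDATED workflow consumes the day-15 MRD category; a record whose
    MRD is unreportable (unsuitable phenotype, no nucleated denominator)
    routes through the configured fallback branch. The trace records every
    rule evaluated with its input value and outcome.
    """
    cfg = validate_tree(tree if tree is not None else load_risk_tree_config())
    workflows = cfg["workflows"]
    if workflow not in workflows:
        raise TreeConfigError(f"workflow {workflow!r} not in tree config ({sorted(workflows)})")
    trace: list[tuple[str, Any, Any]] = []
    group = _traverse(record, workflows[workflow], workflows, trace)
    return RiskAssignment(group=group, workflow=workflow, trace=tuple(trace))
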