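"""MRD quantification: suitability, the Syto13/CD45 denominator correction
factor, corrected MRD percentage, limit-of-detection status and clinical
category.

The raw MRD is the blast-cluster event count as a percentage of the Tube 1
pseudo-Ficoll ("mononuclear") gate. Tube 2 carries the nuclear dye: the
correction factor CF = N / (N - N_SytoNegCD45Neg) re-expresses the result
on a nucleated denominator by subtracting Syto13-/CD45- (non-nucleated)
events, so corrected MRD = raw MRD x CF, capped at 100%. CF > 5 means more
than 80% of the gated "mononuclear" events were non-nucleated — severe
hemodilution — and flags limited sensitivity. The 10-event limit of
detection applies to the gated cluster size, not to the percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

from .config import load_gate_config
from .fcs_io import Sample, TUBE1_SURFACE, TUBE2_SYTO, validate_panel
from .gating import (
    GateResult,
    blast_event_indices,
    default_gates,
    exclude_debris,
    find_blast_clusters,
    marker_positive,
    pseudo_ficoll_gate,
)

__all__ = [
    "CATEGORIES",
    "DiagnosticPhenotype",
    "Tube2Counts",
    "MRDResult",
    "UnquantifiableSampleError",
    "assess_suitability",
    "correction_factor",
    "categorize_mrd",
    "compute_mrd",
    "tube2_counts",
    "quantify_sample",
]

#: ordered clinical MRD categories (Fig. 2-style bins)
CATEGORIES = ("NEG_LT_0.01", "POS_0.01_0.1", "POS_0.1_10", "POS_GT_10")

#: correction factor above which sensitivity is considered limited
CF_DISCLAIMER_THRESHOLD = 5.0

#: minimum qualifying cluster size (events), the limit of detection
LOD_MIN_CLUSTER = 10


class UnquantifiableSampleError(ValueError):
    """No nucleated denominator: every gated Tube 2 event is Syto-/CD45-."""


@dataclass(frozen=True)
class DiagnosticPhenotype:
    """Diagnostic immunophenotype of the leukemic clone."""

    cd19_pos: bool
    cd10_pos: bool
    cd34_pos: bool


@dataclass(frozen=True)
class Tube2Counts:
    """Tube 2 pseudo-Ficoll gate content used for the correction factor."""

    n_pseudo_ficoll: int
    n_syto_neg_cd45_neg: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_syto_neg_cd45_neg <= self.n_pseudo_ficoll:
            raise ValueError(
                f"need 0 <= n_syto_neg_cd45_neg <= n_pseudo_ficoll, got "
                f"({self.n_pseudo_ficoll}, {self.n_syto_neg_cd45_neg})"
            )


@dataclass(frozen=True)
class MRDResult:
    suitable: bool
    blast_events: int
    denominator_raw: int
    correction_factor: float
    mrd_raw_pct: float
    mrd_corrected_pct: float
    lod_met: bool
    category: str
    limited_sensitivity: bool
    phenotype_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.correction_factor < 1.0:
            raise ValueError("correction factor must be >= 1")

    @property
    def reportable(self) -> bool:
        """Whether the MRD value may drive re-classification: unsuitable
        phenotypes and hemodilution-limited (CF > 5) results are reported
        with a disclaimer but do not update the risk group."""
        return self.suitable and not self.limited_sensitivity


def assess_suitability(ph: DiagnosticPhenotype) -> bool:
    """Suitable iff the clone is CD19+CD10+ or CD19+CD34+ at diagnosis."""
    return (ph.cd19_pos and ph.cd10_pos) or (ph.cd19_pos and ph.cd34_pos)


def correction_factor(t2: Tube2Counts) -> float:
    """CF = gated events / (gated events - Syto-CD45- events), >= 1."""
    nucleated = t2.n_pseudo_ficoll - t2.n_syto_neg_cd45_neg
    if nucleated <= 0:
        raise UnquantifiableSampleError(
            "all pseudo-Ficoll events are Syto13-/CD45-: no nucleated denominator"
        )
    return t2.n_pseudo_ficoll / nucleated


def categorize_mrd(mrd_pct: float) -> str:
    """Total partition of [0, 100]%: [0, 0.01) negative; [0.01, 0.1);
    [0.1, 10]; (10, 100] — 'greater than 10%' is strict."""
    if not 0.0 <= mrd_pct <= 100.0:
        raise ValueError(f"MRD percentage {mrd_pct} outside [0, 100]")
    if mrd_pct < 0.01:
        return "NEG_LT_0.01"
    if mrd_pct < 0.1:
        return "POS_0.01_0.1"
    if mrd_pct <= 10.0:
        return "POS_0.1_10"
    return "POS_GT_10"


def compute_mrd(blast_events: int, denominator_raw: int, cf: float,
                suitable: bool = True,
                lod_met: bool | None = None,
                phenotype_used: Sequence[str] = ()) -> MRDResult:
    """Assemble an :class:`MRDResult` from gate counts and the correction.

    ``lod_met`` is normally carried in from gating (a qualifying >= 10-event
    cluster existed); when omitted it defaults to ``blast_events >= 10``.
    When the cluster rule is unmet the category is forced negative.
    Unsuitable samples still produce a structured result, flagged
    unreportable, never a silent skip.
    """
    if denominator_raw < 1:
        raise ValueError("denominator_raw must be >= 1")
    if cf < 1.0:
        raise ValueError("correction factor must be >= 1")
    if blast_events < 0 or blast_events > denominator_raw:
        raise ValueError(
            f"blast_events {blast_events} inconsistent with denominator {denominator_raw}"
        )
    if lod_met is None:
        lod_met = blast_events >= LOD_MIN_CLUSTER
    raw = 100.0 * blast_events / denominator_raw
    corrected = min(100.0, raw * cf)
    category = categorize_mrd(corrected) if lod_met else "NEG_LT_0.01"
    return MRDResult(
        suitable=bool(suitable),
        blast_events=int(blast_events),
        denominator_raw=int(denominator_raw),
        correction_factor=float(cf),
        mrd_raw_pct=raw,
        mrd_corrected_pct=corrected,
        lod_met=bool(lod_met),
        category=category,
        limited_sensitivity=cf > CF_DISCLAIMER_THRESHOLD,
        phenotype_used=tuple(phenotype_used),
    )


# --------------------------------------------------------------------------
# tube-level orchestration

def tube2_counts(tube2: Sample, config: dict[str, Any] | None = None) -> Tube2Counts:
    """Gate Tube 2 (debris exclusion then pseudo-Ficoll) and count the
    Syto13-/CD45- events inside the gate."""
    cfg = config if config is not None else load_gate_config()
    validate_panel(tube2, TUBE2_SYTO)
    nd = exclude_debris(tube2, config=cfg)
    pf = pseudo_ficoll_gate(tube2, nd, config=cfg)
    thr = cfg["thresholds"]
    syto_pos = marker_positive(tube2, "SYTO13", thr["SYTO13"])
    cd45_pos = marker_positive(tube2, "CD45", thr["CD45"])
    both_neg = pf.membership & ~syto_pos & ~cd45_pos
    return Tube2Counts(n_pseudo_ficoll=pf.n_in, n_syto_neg_cd45_neg=int(both_neg.sum()))


def quantify_sample(tube1: Sample, tube2: Sample,
                    phenotype: DiagnosticPhenotype | None = None,
                    config: dict[str, Any] | None = None,
                    return_counts: bool = False):
    """Run the full two-tube quantification for one sample.

    Tube 1: debris exclusion -> pseudo-Ficoll gate -> blast-cluster
    detection (LOD and back-gating applied). Tube 2: correction-factor
    estimation. Returns the :class:`MRDResult` (plus the per-stage gate
    counts when ``return_counts`` is set).
    """
    cfg = config if config is not None else load_gate_config()
    validate_panel(tube1, TUBE1_SURFACE)
    suitable = True if phenotype is None else assess_suitability(phenotype)

    nd = exclude_debris(tube1, config=cfg)
    pf = pseudo_ficoll_gate(tube1, nd, config=cfg)
    calls = find_blast_clusters(tube1, pf, config=cfg)
    blast_idx = blast_event_indices(calls)
    lod_met = len(calls) > 0

    t2 = tube2_counts(tube2, config=cfg)
    cf = correction_factor(t2)
    result = compute_mrd(
        blast_events=len(blast_idx),
        denominator_raw=max(pf.n_in, 1),
        cf=cf,
        suitable=suitable,
        lod_met=lod_met,
        phenotype_used=tuple(sorted({c.phenotype for c in calls})),
    )
    if return_counts:
        counts = {
            "tube1_total": tube1.n_events,
            "tube1_nondebris": nd.n_in,
            "tube1_pseudo_ficoll": pf.n_in,
            "tube1_blast_events": len(blast_idx),
            "tube2_total": tube2.n_events,
            "tube2_pseudo_ficoll": t2.n_pseudo_ficoll,
            "tube2_syto_neg_cd45_neg": t2.n_syto_neg_cd45_neg,
        }
        return result, counts
    return result
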