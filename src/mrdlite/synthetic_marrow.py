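"""Synthetic two-tube bone-marrow samples with known ground truth.

Emulates day-15 post-induction marrow as a mixture of lymphocytes,
monocytes, neutrophils, nucleated erythroid precursors, non-nucleated
residue (RBC/debris) and leukemic blasts, each drawn from a first-order
cytometry model: normal scatter on the linear scale, log10-normal
fluorescence truncated at the detector range. Preparation-method effects
(Ficoll removes neutrophils and most non-nucleated material; bulk lysis
keeps neutrophils and leaves a residue of non-nucleated events scaled by
the hemodilution factor) act multiplicatively on population fractions and
are renormalized, so the relative composition of the nucleated
non-neutrophil compartment is preserved across arms.

Tube 1 (surface panel) and Tube 2 (Syto13/CD235a) are *independent* draws
from the same composition, mirroring the physical two-tube assay: any
between-tube correction must be estimated, never copied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Callable, Sequence

import numpy as np

from .config import load_population_config
from .fcs_io import TUBE1_SURFACE, TUBE2_SYTO, ChannelInfo, Sample
from .risk_engine import CsfFinding, PatientRecord

__all__ = [
    "BULK_LYSIS",
    "FICOLL",
    "POPULATION_LABELS",
    "NUCLEATED_LABELS",
    "MONONUCLEAR_LABELS",
    "BLAST_PHENOTYPES",
    "SpecError",
    "PopulationSpec",
    "SampleSpec",
    "SyntheticTruth",
    "CohortPatient",
    "make_sample_spec",
    "blast_fraction_for_mononuclear_pct",
    "apply_preparation",
    "preparation_recovery",
    "generate_tube_pair",
    "generate_cohort",
]

BULK_LYSIS = "BULK_LYSIS"
FICOLL = "FICOLL"

POPULATION_LABELS = ("LYMPH", "MONO", "NEUT", "ERYTHROID_NUCLEATED", "RBC_DEBRIS", "BLAST")
NUCLEATED_LABELS = ("LYMPH", "MONO", "NEUT", "ERYTHROID_NUCLEATED", "BLAST")
MONONUCLEAR_LABELS = ("LYMPH", "MONO", "ERYTHROID_NUCLEATED", "BLAST")
BLAST_PHENOTYPES = ("CD19_CD10", "CD19_CD34", "CD19_CD10_CD34", "CD10_CD34_NEGATIVE")

TUBE1_CHANNELS = ("FSC", "SSC", "CD45", "CD19", "CD10", "CD34")
TUBE2_CHANNELS = ("FSC", "SSC", "CD45", "SYTO13", "CD235A")


class SpecError(ValueError):
    """Invalid synthetic sample or cohort specification."""


@dataclass(frozen=True)
class PopulationSpec:
    """One mixture component: fraction plus per-channel location/spread.

    Fluorescence means/sds are on the log10 scale; scatter channels (FSC,
    SSC) are on the linear scale.
    """

    label: str
    fraction: float
    channel_means: dict[str, float]
    channel_sds: dict[str, float]
    blast_phenotype: str | None = None

    def __post_init__(self) -> None:
        if self.label not in POPULATION_LABELS:
            raise SpecError(f"unknown population label {self.label!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise SpecError(f"fraction {self.fraction} outside [0, 1]")
        if any(sd <= 0 for sd in self.channel_sds.values()):
            raise SpecError(f"non-positive sd in population {self.label}")
        if self.label == "BLAST":
            if self.blast_phenotype not in BLAST_PHENOTYPES:
                raise SpecError(f"BLAST requires a phenotype from {BLAST_PHENOTYPES}")
        elif self.blast_phenotype is not None:
            raise SpecError("blast_phenotype is only valid on the BLAST population")


@dataclass(frozen=True)
class SampleSpec:
    populations: tuple[PopulationSpec, ...]
    n_events: int
    preparation: str = BULK_LYSIS
    hemodilution_factor: float = 1.0
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        if self.n_events < 1:
            raise SpecError("n_events must be >= 1")
        if self.preparation not in (BULK_LYSIS, FICOLL):
            raise SpecError(f"unknown preparation {self.preparation!r}")
        if self.hemodilution_factor < 1.0:
            raise SpecError("hemodilution_factor must be >= 1")
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"population fractions sum to {total!r}, not 1")
        n_blast = sum(1 for p in self.populations if p.label == "BLAST")
        if n_blast != 1:
            raise SpecError(f"exactly one BLAST population required, found {n_blast}")

    @property
    def blast(self) -> PopulationSpec:
        return next(p for p in self.populations if p.label == "BLAST")

    def fraction_of(self, label: str) -> float:
        return sum(p.fraction for p in self.populations if p.label == label)


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-event population labels for both tubes plus the generating spec."""

    labels_tube1: np.ndarray  # array of label strings, length n_events
    labels_tube2: np.ndarray
    spec: SampleSpec

    def __post_init__(self) -> None:
        if len(self.labels_tube1) != self.spec.n_events:
            raise SpecError("tube-1 label count does not match n_events")

    def _fraction(self, labels: np.ndarray, num: Sequence[str], den: Sequence[str]) -> float:
        d = int(np.isin(labels, list(den)).sum())
        if d == 0:
            return 0.0
        return float(np.isin(labels, list(num)).sum() / d)

    @property
    def true_blast_fraction_of_nucleated(self) -> float:
        """Blast share of nucleated events in tube 1, recomputed from labels."""
        return self._fraction(self.labels_tube1, ["BLAST"], NUCLEATED_LABELS)

    @property
    def true_blast_fraction_of_mononuclear(self) -> float:
        """Blast share of nucleated *mononuclear* events (the MRD denominator)."""
        return self._fraction(self.labels_tube1, ["BLAST"], MONONUCLEAR_LABELS)


# --------------------------------------------------------------------------
# spec construction

def _population_from_config(label: str, fraction: float, cfg: dict[str, Any],
                            blast_phenotype: str | None = None) -> PopulationSpec:
    pcfg = cfg["populations"][label]
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for ch, (m, s) in pcfg["scatter"].items():
        means[ch], sds[ch] = float(m), float(s)
    for ch, (m, s) in pcfg["fluor"].items():
        means[ch], sds[ch] = float(m), float(s)
    if label == "BLAST":
        pos = pcfg["blast_marker_positive"]
        neg = pcfg["blast_marker_negative"]
        cd10 = pos if "CD10" in blast_phenotype and blast_phenotype != "CD10_CD34_NEGATIVE" else neg
        cd34 = pos if "CD34" in blast_phenotype and blast_phenotype != "CD10_CD34_NEGATIVE" else neg
        means["CD10"], sds["CD10"] = float(cd10[0]), float(cd10[1])
        means["CD34"], sds["CD34"] = float(cd34[0]), float(cd34[1])
    return PopulationSpec(label, fraction, means, sds, blast_phenotype if label == "BLAST" else None)


def make_sample_spec(blast_fraction_of_nucleated: float,
                     n_events: int = 500_000,
                     preparation: str = BULK_LYSIS,
                     hemodilution_factor: float = 1.0,
                     seed: int = 0,
                     blast_phenotype: str = "CD19_CD10",
                     sample_id: str = "synthetic",
                     config: dict[str, Any] | None = None) -> SampleSpec:
    """Build a raw (pre-preparation) day-15 marrow spec from the default
    composition, carving ``blast_fraction_of_nucleated`` out of the
    nucleated compartment."""
    if not 0.0 <= blast_fraction_of_nucleated <= 1.0:
        raise SpecError("blast fraction must be in [0, 1]")
    cfg = config if config is not None else load_population_config()
    comp = cfg["composition"]
    debris = float(comp["rbc_debris_fraction"])
    nucleated = 1.0 - debris
    f = blast_fraction_of_nucleated
    pops = []
    for label, share in comp["nucleated"].items():
        pops.append(_population_from_config(label, nucleated * float(share) * (1.0 - f), cfg))
    pops.append(_population_from_config("BLAST", nucleated * f, cfg, blast_phenotype))
    pops.append(_population_from_config("RBC_DEBRIS", debris, cfg))
    # absorb float rounding into the largest component so fractions sum to 1
    total = sum(p.fraction for p in pops)
    big = max(range(len(pops)), key=lambda i: pops[i].fraction)
    pops[big] = replace(pops[big], fraction=pops[big].fraction + (1.0 - total))
    return SampleSpec(tuple(pops), n_events, preparation, hemodilution_factor, seed, sample_id)


def blast_fraction_for_mononuclear_pct(mrd_pct: float,
                                       config: dict[str, Any] | None = None) -> float:
    """Invert the default composition: the blast fraction of *nucleated*
    cells that yields a target blast share ``mrd_pct`` (in %) of the
    nucleated mononuclear compartment."""
    cfg = config if config is not None else load_population_config()
    mono_share = sum(v for k, v in cfg["composition"]["nucleated"].items() if k != "NEUT")
    m = mrd_pct / 100.0
    if not 0.0 <= m < 1.0:
        raise SpecError("target mononuclear MRD must be in [0, 100)%")
    return mono_share * m / (1.0 - m * (1.0 - mono_share))


# --------------------------------------------------------------------------
# preparation effects

def apply_preparation(spec: SampleSpec, config: dict[str, Any] | None = None) -> SampleSpec:
    """Apply preparation-method retention factors and renormalize.

    FICOLL multiplies the neutrophil fraction by the neutrophil retention
    factor and RBC/debris by the Ficoll debris retention factor; BULK_LYSIS
    multiplies RBC/debris by the lysis-residual factor times the
    hemodilution factor. All other fractions are untouched before
    renormalization, preserving the relative nucleated non-neutrophil
    composition in both arms.
    """
    cfg = config if config is not None else load_population_config()
    prep = cfg["preparation"]
    scaled: list[float] = []
    for p in spec.populations:
        frac = p.fraction
        if spec.preparation == FICOLL:
            if p.label == "NEUT":
                frac *= float(prep["ficoll_neut_retention"])
            elif p.label == "RBC_DEBRIS":
                frac *= float(prep["ficoll_debris_retention"])
        else:  # BULK_LYSIS
            if p.label == "RBC_DEBRIS":
                frac *= float(prep["bulk_lysis_debris_residual"]) * spec.hemodilution_factor
        scaled.append(frac)
    total = sum(scaled)
    fracs = [f / total for f in scaled]
    # renormalized fractions must still sum to exactly 1 for the spec check
    big = max(range(len(fracs)), key=lambda i: fracs[i])
    fracs[big] += 1.0 - sum(fracs)
    out = [replace(p, fraction=f) for p, f in zip(spec.populations, fracs)]
    return replace(spec, populations=tuple(out))


def preparation_recovery(spec: SampleSpec, config: dict[str, Any] | None = None) -> float:
    """Fraction of the original event mass surviving the preparation step
    (used to scale acquired-event counts between paired arms)."""
    cfg = config if config is not None else load_population_config()
    prep = cfg["preparation"]
    total = 0.0
    for p in spec.populations:
        frac = p.fraction
        if spec.preparation == FICOLL:
            if p.label == "NEUT":
                frac *= float(prep["ficoll_neut_retention"])
            elif p.label == "RBC_DEBRIS":
                frac *= float(prep["ficoll_debris_retention"])
        else:
            if p.label == "RBC_DEBRIS":
                frac *= float(prep["bulk_lysis_debris_residual"]) * spec.hemodilution_factor
        total += frac
    return total


# --------------------------------------------------------------------------
# event generation

def _draw_tube(spec: SampleSpec, channels: Sequence[str], rng: np.random.Generator,
               cfg: dict[str, Any]) -> tuple[np.ndarray, np.ndarray]:
    """Draw one tube's event matrix plus per-event labels."""
    n = spec.n_events
    fractions = np.array([p.fraction for p in spec.populations])
    counts = rng.multinomial(n, fractions / fractions.sum())
    scatter_chs = set(cfg.get("scatter_channels", ["FSC", "SSC"]))
    scatter_max = float(cfg.get("scatter_range", 1000.0))
    decades = math.log10(float(cfg.get("detector_range", 1e5)))

    events = np.empty((n, len(channels)), dtype=np.float64)
    labels = np.empty(n, dtype=object)
    start = 0
    for pop, k in zip(spec.populations, counts):
        if k == 0:
            continue
        sl = slice(start, start + k)
        labels[sl] = pop.label
        for j, ch in enumerate(channels):
            m, s = pop.channel_means[ch], pop.channel_sds[ch]
            draw = rng.normal(m, s, size=k)
            if ch in scatter_chs:
                events[sl, j] = np.clip(draw, 0.0, scatter_max)
            else:
                events[sl, j] = 10.0 ** np.clip(draw, 0.0, decades)
        start += k
    perm = rng.permutation(n)
    return events[perm], labels[perm].astype(str)


def generate_tube_pair(spec: SampleSpec,
                       config: dict[str, Any] | None = None
                       ) -> tuple[Sample, Sample, SyntheticTruth]:
    """Generate the paired surface and Syto13 tubes for one sample.

    Both tubes are independent, seeded draws from the same composition.
    Syto13 is high for nucleated labels and low for RBC/debris; CD235a is
    high for erythroid-lineage labels.
    """
    cfg = config if config is not None else load_population_config()
    for ch_list in (TUBE1_CHANNELS, TUBE2_CHANNELS):
        for p in spec.populations:
            missing = [c for c in ch_list if c not in p.channel_means]
            if missing:
                raise SpecError(f"population {p.label} lacks channels {missing}")
    ss = np.random.SeedSequence(spec.seed)
    rng1, rng2 = (np.random.default_rng(c) for c in ss.spawn(2))
    ev1, lab1 = _draw_tube(spec, TUBE1_CHANNELS, rng1, cfg)
    ev2, lab2 = _draw_tube(spec, TUBE2_CHANNELS, rng2, cfg)

    det = float(cfg.get("detector_range", 1e5))
    sc = float(cfg.get("scatter_range", 1000.0))

    def mk_channels(names: Sequence[str]) -> list[ChannelInfo]:
        return [
            ChannelInfo(nm, sc if nm in ("FSC", "SSC") else det,
                        "linear" if nm in ("FSC", "SSC") else "log10")
            for nm in names
        ]

    volume = 200.0 if spec.hemodilution_factor > 1.5 else 100.0
    t1 = Sample(spec.sample_id, TUBE1_SURFACE, ev1, mk_channels(TUBE1_CHANNELS),
                acquired_events=spec.n_events, volume_ul=volume)
    t2 = Sample(spec.sample_id, TUBE2_SYTO, ev2, mk_channels(TUBE2_CHANNELS),
                acquired_events=spec.n_events, volume_ul=volume)
    return t1, t2, SyntheticTruth(lab1, lab2, spec)


# --------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class CohortPatient:
    sample_spec: SampleSpec
    record: PatientRecord
    true_blast_fraction_of_nucleated: float
    diagnostic_cd19: bool = True
    diagnostic_cd10: bool = True
    diagnostic_cd34: bool = False


def _make_sampler(desc: dict[str, Any] | Callable[[np.random.Generator, int], np.ndarray]
                  ) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Blast-fraction samplers: loguniform / uniform / fixed / two_part
    (exactly ``n_zero`` MRD-negative patients, the rest log-uniform)."""
    if callable(desc):
        return desc
    kind = desc.get("kind")
    if kind == "loguniform":
        low, high = float(desc["low"]), float(desc["high"])
        if not 0 < low < high:
            raise SpecError(f"loguniform requires 0 < low < high, got ({low}, {high})")
        return lambda rng, n: np.exp(rng.uniform(np.log(low), np.log(high), size=n))
    if kind == "uniform":
        low, high = float(desc["low"]), float(desc["high"])
        if not 0 <= low < high:
            raise SpecError(f"uniform requires low < high, got ({low}, {high})")
        return lambda rng, n: rng.uniform(low, high, size=n)
    if kind == "fixed":
        values = np.asarray(desc["values"], dtype=float)

        def fixed(rng: np.random.Generator, n: int) -> np.ndarray:
            if len(values) != n:
                raise SpecError(f"fixed sampler has {len(values)} values for {n} patients")
            return values.copy()

        return fixed
    if kind == "two_part":
        n_zero = int(desc["n_zero"])
        low, high = float(desc["low"]), float(desc["high"])
        if not 0 < low < high:
            raise SpecError(f"two_part requires 0 < low < high, got ({low}, {high})")

        def two_part(rng: np.random.Generator, n: int) -> np.ndarray:
            if n_zero > n:
                raise SpecError(f"n_zero {n_zero} exceeds cohort size {n}")
            vals = np.exp(rng.uniform(np.log(low), np.log(high), size=n))
            zero_idx = rng.choice(n, size=n_zero, replace=False)
            vals[zero_idx] = 0.0
            return vals

        return two_part
    raise SpecError(f"unknown blast-fraction sampler kind {kind!r}")


def generate_cohort(n_patients: int,
                    blast_fraction_sampler: dict[str, Any] | Callable,
                    seed: int = 0,
                    n_events: int = 500_000,
                    preparation: str = BULK_LYSIS,
                    n_unsuitable: int = 0,
                    hemodilution_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
                    config: dict[str, Any] | None = None) -> list[CohortPatient]:
    """Generate per-patient sample specs plus clinical records.

    Blast fractions (of nucleated cells) come from the configured sampler;
    clinical covariates (age, WBC, CSF findings, day-8 peripheral blasts,
    day-33 marrow blasts) are drawn from simple distributions typical of a
    pediatric B-ALL cohort. ``n_unsuitable`` patients are assigned a
    CD10-/CD34- diagnostic phenotype (unsuitable for the simplified assay).
    Fully seeded and reproducible.
    """
    if n_patients < 1:
        raise SpecError("n_patients must be >= 1")
    if not 0 <= n_unsuitable <= n_patients:
        raise SpecError("n_unsuitable must be in [0, n_patients]")
    cfg = config if config is not None else load_population_config()
    sampler = _make_sampler(blast_fraction_sampler)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    fractions = np.asarray(sampler(rng, n_patients), dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise SpecError("sampled blast fractions fall outside [0, 1]")
    hemo = (np.ones(n_patients) if hemodilution_sampler is None
            else np.asarray(hemodilution_sampler(rng, n_patients), dtype=float))
    unsuitable_idx = set(rng.choice(n_patients, size=n_unsuitable, replace=False).tolist()) \
        if n_unsuitable else set()

    patients: list[CohortPatient] = []
    seeds = ss.spawn(n_patients)
    for i in range(n_patients):
        child = int(seeds[i].generate_state(1)[0] % (2 ** 31))
        f = float(fractions[i])
        age = float(rng.uniform(1.0, 17.0))
        wbc = float(np.clip(rng.lognormal(mean=np.log(10_000), sigma=1.0), 500, 600_000))
        csf_blasts = bool(rng.random() < 0.08)
        csf = CsfFinding(
            wbc_per_mm3=float(rng.lognormal(0.5, 1.0)) if csf_blasts else float(rng.uniform(0, 3)),
            blasts_present=csf_blasts,
            rbc_per_mm3=float(rng.lognormal(1.0, 1.5)),
            hours_after_therapy_start=float(rng.uniform(0, 48)),
            cranial_nerve_palsy=bool(rng.random() < 0.01),
            cerebral_mass=bool(rng.random() < 0.005),
        )
        # day-8 peripheral blasts loosely tied to the day-15 burden
        day8 = float(rng.lognormal(np.log(50 + 2e4 * f + 1e-12), 1.0))
        day33 = float(np.clip(rng.lognormal(np.log(1.0 + 40 * f), 0.5), 0.0, 100.0))
        record = PatientRecord(
            patient_id=f"P{i:04d}",
            age_years=age,
            wbc_per_ul=wbc,
            lineage="B_PRECURSOR",
            csf=csf,
            day8_peripheral_blasts_per_mm3=day8,
            day33_marrow_blast_pct=day33,
        )
        unsuitable = i in unsuitable_idx
        phenotype = "CD10_CD34_NEGATIVE" if unsuitable else ("CD19_CD10" if rng.random() < 0.7 else "CD19_CD34")
        spec = make_sample_spec(
            blast_fraction_of_nucleated=f,
            n_events=n_events,
            preparation=preparation,
            hemodilution_factor=float(hemo[i]),
            seed=child,
            blast_phenotype=phenotype,
            sample_id=record.patient_id,
            config=cfg,
        )
        patients.append(CohortPatient(
            sample_spec=spec,
            record=record,
            true_blast_fraction_of_nucleated=f,
            diagnostic_cd19=True,
            diagnostic_cd10=(not unsuitable) and phenotype in ("CD19_CD10", "CD19_CD10_CD34"),
            diagnostic_cd34=(not unsuitable) and phenotype in ("CD19_CD34", "CD19_CD10_CD34"),
        ))
    return patients
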