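"""Experiment design: genotypes, parent/NIL pairing, watering and imaging schedules.

The reference design is a greenhouse pot experiment with six wheat genotypes
(three elite parents, each paired with a near-isogenic line carrying a wild
emmer introgression), two watering treatments and ten replicates per
genotype x treatment.  Plants are imaged daily until late ripening and every
second day thereafter; drought is imposed by stepping the watering target
down from 90% plant-available water content (PAWC) to 30% (mild) and later
20% (severe).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

CONTROL = "control"
STRESS = "stress"


@dataclass(frozen=True)
class GenotypeSpec:
    """One genotype: an elite parent or the NIL paired with it."""

    name: str
    role: str  # "parent" or "nil"
    partner: str = ""  # name of the paired genotype; empty if unpaired

    def __post_init__(self) -> None:
        if self.role not in ("parent", "nil"):
            raise ValueError(f"role must be 'parent' or 'nil', got {self.role!r}")
        if self.role == "nil" and not self.partner:
            raise ValueError(f"NIL {self.name!r} must name its recurrent parent")


@dataclass(frozen=True)
class WateringPhase:
    """A watering target holding from ``start_das`` until the next phase."""

    start_das: int
    target_pawc: float  # fraction of plant-available water content in (0, 1]

    def __post_init__(self) -> None:
        if self.start_das < 1:
            raise ValueError("start_das must be a positive DAS")
        if not 0.0 < self.target_pawc <= 1.0:
            raise ValueError("target_pawc must lie in (0, 1]")


@dataclass(frozen=True)
class TemperaturePhase:
    """Day/night temperature set point, metadata only (not used numerically)."""

    start_das: int
    night_c: float
    day_c: float


@dataclass
class ExperimentDesign:
    """Full description of one HTP experiment.

    Parameters
    ----------
    genotypes
        All genotypes on the platform; NILs reference their parent via
        ``partner`` and pairing must be symmetric.
    n_rep
        Biological replicates per genotype x treatment (>= 2).
    watering
        Per-treatment ordered lists of :class:`WateringPhase`.
    imaging_daily_until, imaging_stride_after, last_das
        Imaging cadence: every day up to ``imaging_daily_until``, then every
        ``imaging_stride_after`` days up to ``last_das``.
    maturity_quorum
        Fraction of replicates that must still be on the platform for a
        genotype to count as not yet mature (default 7/10).
    """

    genotypes: list[GenotypeSpec]
    n_rep: int
    watering: dict[str, list[WateringPhase]]
    imaging_daily_until: int
    imaging_stride_after: int
    last_das: int
    maturity_quorum: float = 0.7
    temperature: list[TemperaturePhase] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")
        if self.imaging_daily_until > self.last_das:
            raise ValueError("imaging_daily_until must not exceed last_das")
        if self.imaging_stride_after < 1:
            raise ValueError("imaging_stride_after must be >= 1")
        if not 0.0 < self.maturity_quorum <= 1.0:
            raise ValueError("maturity_quorum must lie in (0, 1]")
        names = {g.name for g in self.genotypes}
        if len(names) != len(self.genotypes):
            raise ValueError("genotype names must be unique")
        by_name = {g.name: g for g in self.genotypes}
        for g in self.genotypes:
            if g.role == "nil":
                parent = by_name.get(g.partner)
                if parent is None or parent.role != "parent":
                    raise ValueError(f"NIL {g.name!r} has no parent {g.partner!r}")
                if parent.partner and parent.partner != g.name:
                    raise ValueError(f"pairing of {g.name!r} is not symmetric")
        for treatment, phases in self.watering.items():
            starts = [p.start_das for p in phases]
            if not phases or starts != sorted(starts) or len(set(starts)) != len(starts):
                raise ValueError(
                    f"watering phases for {treatment!r} must be non-empty, "
                    "ordered and non-overlapping"
                )

    @property
    def treatments(self) -> list[str]:
        return list(self.watering)

    def pairs(self) -> list[tuple[str, str]]:
        """(parent, nil) name pairs in declaration order."""
        return [(g.partner, g.name) for g in self.genotypes if g.role == "nil"]


def build_default_design() -> ExperimentDesign:
    """The reference wheat drought design.

    Six genotypes in three parent/NIL pairs, ten replicates each in a
    well-watered control (90% PAWC throughout) and a progressive drought
    treatment (90% PAWC until DAS 30, 30% from DAS 31, 20% from DAS 64).
    Imaging is daily until DAS 95 and every 2 days until DAS 121.
    """
    genotypes = [
        GenotypeSpec("BarNir", "parent", "NIL-B-7A-2"),
        GenotypeSpec("NIL-B-7A-2", "nil", "BarNir"),
        GenotypeSpec("Zahir", "parent", "NIL-Z-7A-5"),
        GenotypeSpec("NIL-Z-7A-5", "nil", "Zahir"),
        GenotypeSpec("Uzan", "parent", "NIL-U-2B-3"),
        GenotypeSpec("NIL-U-2B-3", "nil", "Uzan"),
    ]
    watering = {
        CONTROL: [WateringPhase(1, 0.90)],
        STRESS: [WateringPhase(1, 0.90), WateringPhase(31, 0.30), WateringPhase(64, 0.20)],
    }
    temperature = [
        TemperaturePhase(1, 12.0, 16.0),
        TemperaturePhase(31, 16.0, 20.0),
        TemperaturePhase(62, 20.0, 24.0),
    ]
    return ExperimentDesign(
        genotypes=genotypes,
        n_rep=10,
        watering=watering,
        imaging_daily_until=95,
        imaging_stride_after=2,
        last_das=121,
        maturity_quorum=0.7,
        temperature=temperature,
    )


def imaging_days(design: ExperimentDesign) -> list[int]:
    """Ordered DAS on which plants are imaged under ``design``."""
    days = list(range(1, design.imaging_daily_until + 1))
    days += list(
        range(
            design.imaging_daily_until + 1,
            design.last_das + 1,
            design.imaging_stride_after,
        )
    )
    return days


def pawc_on_day(design: ExperimentDesign, treatment: str, das: int) -> float:
    """Watering target (fraction of PAWC) in force on a given DAS.

    The schedule is a right-continuous step function: the target of the
    latest phase whose ``start_das`` is <= ``das`` applies.
    """
    if treatment not in design.watering:
        raise KeyError(f"unknown treatment {treatment!r}")
    if not 1 <= das <= design.last_das:
        raise ValueError(f"DAS {das} outside 1..{design.last_das}")
    target = None
    for phase in design.watering[treatment]:
        if phase.start_das <= das:
            target = phase.target_pawc
    if target is None:  # before the first phase: fall back to its target
        target = design.watering[treatment][0].target_pawc
    return target


def stress_onset(design: ExperimentDesign, treatment: str = STRESS) -> int | None:
    """First DAS on which the watering target drops below the initial one."""
    phases = design.watering[treatment]
    for phase in phases[1:]:
        if phase.target_pawc < phases[0].target_pawc:
            return phase.start_das
    return None


# ---------------------------------------------------------------------------
# YAML serialization


def design_to_yaml(design: ExperimentDesign, path) -> None:
    doc = {
        "genotypes": [asdict(g) for g in design.genotypes],
        "n_rep": design.n_rep,
        "watering": {
            t: [{"start_das": p.start_das, "target_pawc": p.target_pawc} for p in ps]
            for t, ps in design.watering.items()
        },
        "imaging_daily_until": design.imaging_daily_until,
        "imaging_stride_after": design.imaging_stride_after,
        "last_das": design.last_das,
        "maturity_quorum": design.maturity_quorum,
        "temperature": [asdict(p) for p in design.temperature],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def design_from_yaml(path) -> ExperimentDesign:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return ExperimentDesign(
        genotypes=[GenotypeSpec(**g) for g in doc["genotypes"]],
        n_rep=int(doc["n_rep"]),
        watering={
            t: [WateringPhase(int(p["start_das"]), float(p["target_pawc"])) for p in ps]
            for t, ps in doc["watering"].items()
        },
        imaging_daily_until=int(doc["imaging_daily_until"]),
        imaging_stride_after=int(doc["imaging_stride_after"]),
        last_das=int(doc["last_das"]),
        maturity_quorum=float(doc.get("maturity_quorum", 0.7)),
        temperature=[TemperaturePhase(**p) for p in doc.get("temperature", [])],
    )
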