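"""Per-patient cost construction for each prehospital analgesic strategy.

All arithmetic — strategy totals, casemix weighting, incremental costs — is
done on unrounded GBP values; rounding to the penny (half-up) happens only at
reporting. That discipline matters: the methoxyflurane-vs-Entonox increment
is 18.8901 - 6.5950 = 12.2951 -> 12.30, whereas differencing the rounded
figures gives 18.89 - 6.60 = 12.29.

The parenteral component lists reconstruct the stated costing: single use of
tourniquet, cannula, cannula pack, syringe and drawing-up needle; 3 (morphine)
or 2 (paracetamol) sodium-chloride flush ampoules plus one drug ampoule/vial;
a giving set for paracetamol infusion; and a paramedic-backup provision of
one ambulance incident per 50 patients. The combined strategy counts the
shared consumables and the backup provision once, uses both drugs, the giving
set and 5 flush ampoules. Any other pain-management costs are assumed to net
to zero.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal


class CostConfigError(ValueError):
    """Invalid cost schedule, assumptions or strategy label."""


def round_gbp(value: float) -> float:
    """Round to the penny, half-up (reporting only)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs in GBP (ambulance-service perspective)."""

    methoxyflurane_dose: float = 17.89
    entonox_cylinder_rental_month: float = 4.84
    entonox_exchange_refill: float = 6.93
    filter_mouthpiece: float = 0.71
    morphine_ampoule: float = 1.145
    giving_set: float = 0.43
    paracetamol_vial: float = 1.20
    cannula: float = 0.53
    cannula_pack: float = 0.70
    syringe: float = 0.04
    needle: float = 0.04
    tourniquet: float = 0.09
    sodium_chloride_ampoule: float = 0.324
    ambulance_incident: float = 209.38

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise CostConfigError(f"unit cost {name} must be positive")

    def scaled(self, k: float) -> "CostSchedule":
        return CostSchedule(**{n: v * k for n, v in asdict(self).items()})


@dataclass(frozen=True)
class CostingAssumptions:
    """Usage, consumable, backup and casemix assumptions.

    The methoxyflurane usage rate (doses prepared per treated patient)
    captures wastage and second dosing; the average Entonox patient is
    assumed to use half an ED-size cylinder; parenteral strategies carry a
    paramedic-backup provision at one ambulance incident per 50 patients;
    the parenteral casemix is 40% morphine, 20% paracetamol, 40% combined.
    """

    methoxyflurane_doses_used: int = 510
    methoxyflurane_patients: int = 483
    entonox_cylinder_share: float = 0.5
    nacl_ampoules_morphine: int = 3
    nacl_ampoules_paracetamol: int = 2
    backup_rate: float = 1.0 / 50.0
    casemix_weights: dict[str, float] = field(
        default_factory=lambda: {"morphine": 0.40, "paracetamol": 0.20, "combined": 0.40}
    )

    def __post_init__(self) -> None:
        if self.methoxyflurane_patients <= 0:
            raise CostConfigError("methoxyflurane_patients must be positive")
        if not 0.0 < self.backup_rate <= 1.0:
            raise CostConfigError("backup_rate must lie in (0, 1]")
        if abs(sum(self.casemix_weights.values()) - 1.0) > 1e-9:
            raise CostConfigError("casemix weights must sum to 1")

    @property
    def usage_rate(self) -> float:
        return self.methoxyflurane_doses_used / self.methoxyflurane_patients


@dataclass
class CostResult:
    """Per-patient cost with its component breakdown (GBP)."""

    strategy: str
    breakdown: dict[str, float]

    @property
    def per_patient_unrounded(self) -> float:
        return sum(self.breakdown.values())

    @property
    def per_patient_reported(self) -> float:
        return round_gbp(self.per_patient_unrounded)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "per_patient_unrounded": self.per_patient_unrounded,
            "per_patient_reported": self.per_patient_reported,
            "breakdown": dict(self.breakdown),
        }


def cost_methoxyflurane(
    schedule: CostSchedule | None = None,
    assumptions: CostingAssumptions | None = None,
) -> CostResult:
    """Dose price times the observed rate of use (doses per treated patient)."""
    schedule = schedule or CostSchedule()
    assumptions = assumptions or CostingAssumptions()
    return CostResult(
        strategy="methoxyflurane",
        breakdown={
            "doses": schedule.methoxyflurane_dose * assumptions.usage_rate,
        },
    )


def cost_entonox(
    schedule: CostSchedule | None = None,
    assumptions: CostingAssumptions | None = None,
) -> CostResult:
    """Breathing filter/mouthpiece plus the apportioned cylinder share."""
    schedule = schedule or CostSchedule()
    assumptions = assumptions or CostingAssumptions()
    share = assumptions.entonox_cylinder_share
    return CostResult(
        strategy="entonox",
        breakdown={
            "filter_mouthpiece": schedule.filter_mouthpiece,
            "cylinder": share
            * (schedule.entonox_cylinder_rental_month + schedule.entonox_exchange_refill),
        },
    )


def _iv_consumables(schedule: CostSchedule) -> dict[str, float]:
    return {
        "tourniquet": schedule.tourniquet,
        "cannula": schedule.cannula,
        "cannula_pack": schedule.cannula_pack,
        "syringe": schedule.syringe,
        "needle": schedule.needle,
    }


def cost_parenteral(
    schedule: CostSchedule | None = None,
    assumptions: CostingAssumptions | None = None,
    strategy: str = "morphine",
) -> CostResult:
    """Per-patient cost of an intravenous strategy.

    ``strategy`` is ``morphine``, ``paracetamol`` or ``combined``; the
    combined strategy counts shared consumables and the backup provision
    once and pools both drugs' flush ampoules.
    """
    schedule = schedule or CostSchedule()
    assumptions = assumptions or CostingAssumptions()
    nacl = schedule.sodium_chloride_ampoule
    backup = assumptions.backup_rate * schedule.ambulance_incident
    breakdown = _iv_consumables(schedule)
    if strategy == "morphine":
        breakdown["sodium_chloride"] = assumptions.nacl_ampoules_morphine * nacl
        breakdown["morphine"] = schedule.morphine_ampoule
    elif strategy == "paracetamol":
        breakdown["giving_set"] = schedule.giving_set
        breakdown["sodium_chloride"] = assumptions.nacl_ampoules_paracetamol * nacl
        breakdown["paracetamol"] = schedule.paracetamol_vial
    elif strategy == "combined":
        breakdown["giving_set"] = schedule.giving_set
        breakdown["sodium_chloride"] = (
            assumptions.nacl_ampoules_morphine + assumptions.nacl_ampoules_paracetamol
        ) * nacl
        breakdown["morphine"] = schedule.morphine_ampoule
        breakdown["paracetamol"] = schedule.paracetamol_vial
    else:
        raise CostConfigError(f"unknown parenteral strategy: {strategy!r}")
    breakdown["paramedic_backup"] = backup
    return CostResult(strategy=strategy, breakdown=breakdown)


def cost_casemix(
    costs: dict[str, CostResult] | None = None,
    weights: dict[str, float] | None = None,
    schedule: CostSchedule | None = None,
    assumptions: CostingAssumptions | None = None,
) -> CostResult:
    """Casemix-weighted mean of the unrounded parenteral per-patient costs."""
    assumptions = assumptions or CostingAssumptions()
    weights = weights if weights is not None else assumptions.casemix_weights
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise CostConfigError("casemix weights must sum to 1")
    if costs is None:
        costs = {
            s: cost_parenteral(schedule, assumptions, s) for s in weights
        }
    breakdown = {
        f"{name} (w={w:g})": w * costs[name].per_patient_unrounded
        for name, w in weights.items()
    }
    return CostResult(strategy="parenteral_casemix", breakdown=breakdown)


def incremental_cost(a: CostResult, b: CostResult) -> float:
    """Reported incremental cost per treated patient, a minus b.

    Computed on the unrounded scale and rounded once for reporting.
    """
    return round_gbp(a.per_patient_unrounded - b.per_patient_unrounded)


def full_cost_report(
    schedule: CostSchedule | None = None,
    assumptions: CostingAssumptions | None = None,
) -> dict:
    """All per-strategy and incremental figures, reported and unrounded."""
    schedule = schedule or CostSchedule()
    assumptions = assumptions or CostingAssumptions()
    methox = cost_methoxyflurane(schedule, assumptions)
    entonox = cost_entonox(schedule, assumptions)
    strategies = {
        s: cost_parenteral(schedule, assumptions, s)
        for s in ("morphine", "paracetamol", "combined")
    }
    casemix = cost_casemix(strategies, assumptions.casemix_weights)
    results = {
        "methoxyflurane": methox,
        "entonox": entonox,
        **strategies,
        "parenteral_casemix": casemix,
    }
    return {
        "per_patient": {k: v.to_dict() for k, v in results.items()},
        "incremental": {
            "methoxyflurane_vs_entonox": incremental_cost(methox, entonox),
            "methoxyflurane_vs_casemix": incremental_cost(methox, casemix),
        },
    }


def report_to_text(report: dict) -> str:
    lines = [f"{'strategy':<22s}{'per patient (GBP)':>20s}"]
    for name, res in report["per_patient"].items():
        lines.append(f"{name:<22s}{res['per_patient_reported']:>20.2f}")
    lines.append("")
    for name, val in report["incremental"].items():
        lines.append(f"{name:<38s}{val:>6.2f}")
    return "\n".join(lines)


def report_to_json(report: dict, **kwargs) -> str:
    return json.dumps(report, indent=2, sort_keys=True, **kwargs)


def schedule_from_json(text: str) -> tuple[CostSchedule, CostingAssumptions]:
    """Load a schedule/assumptions pair from a JSON document."""
    doc = json.loads(text)
    return (
        CostSchedule(**doc.get("schedule", {})),
        CostingAssumptions(**doc.get("assumptions", {})),
    )
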