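"""Episode data model, inclusion filtering, baseline imputation and attrition.

An *episode* is one patient-treatment unit: a treatment arm, episode-level
covariates, and an ordered sequence of timed VNPS observations. Observation
times are in minutes relative to administration of the analgesic of interest
(administration = 0; negative times are scores taken before administration).

The estimation sample is built by, in order:

1. adult (age >= 18);
2. trauma presentation;
3. conscious (GCS-eligible);
4. baseline moderate-to-severe pain;
5. at least two pain scores, the first taken at or before administration and
   the remainder during the analgesic's period of effect;
6. for comparator arms, the named analgesic is the only analgesic recorded.

Stages 1-4 mirror the methoxyflurane licence indication. In the study design
they are imposed strictly on comparator arms extracted from the ambulance
database, while methoxyflurane episodes that violate them are retained with
ineligibility flags (which enter the model as covariates) and are only removed
for the per-protocol sample. ``FilterCriteria`` encodes that default and is
fully configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .scale import is_moderate_to_severe, validate_vnps

ARMS = ("methoxyflurane", "entonox", "morphine_iv", "paracetamol_iv")
COMPARATOR_ARMS = ("entonox", "morphine_iv", "paracetamol_iv")

INELIGIBILITY_FLAGS = (
    "under_18",
    "pain_mild_none_baseline",
    "gcs_ineligible_missing",
    "trauma_ineligible",
)
MEDICINE_USE_FLAGS = (
    "nonadherence",
    "side_effect",
    "discontinue_early",
    "influence_entonox",
    "influence_potency_1",
    "influence_potency_2",
    "influence_potency_3",
)
FLAG_COLUMNS = INELIGIBILITY_FLAGS[:2] + ("trauma_ineligible",) + MEDICINE_USE_FLAGS

#: Long-format CSV columns, one row per observation.
CSV_COLUMNS = (
    "episode_id",
    "arm",
    "time_min",
    "vnps",
    "sex",
    "age_years",
    "trauma_class",
    "gcs_flag",
    "under_18",
    "pain_mild_none_baseline",
    "trauma_ineligible",
    "nonadherence",
    "side_effect",
    "discontinue_early",
    "influence_entonox",
    "influence_potency_1",
    "influence_potency_2",
    "influence_potency_3",
    "other_analgesics",
)


class EpisodeError(ValueError):
    """Malformed episode or unsupported input."""


class ImputationError(EpisodeError):
    """Baseline imputation impossible (no score at or before time 0)."""


class FilterConfigError(EpisodeError):
    """Invalid filter configuration (e.g. unknown arm label)."""


@dataclass(frozen=True)
class PainObservation:
    """One timed VNPS measurement within an episode."""

    time_min: float
    score: int

    def __post_init__(self) -> None:
        t = float(self.time_min)
        if not t == t or t in (float("inf"), float("-inf")):
            raise EpisodeError(f"non-finite observation time: {self.time_min!r}")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "score", validate_vnps(self.score))


@dataclass(frozen=True)
class Episode:
    """Patient-treatment unit with its ordered pain-score sequence.

    ``sex`` is coded F=0, M=1. ``trauma_class`` follows the seven-group
    presentation taxonomy (1 = limb injury/fall reference group, ..., 7 =
    other). ``gcs_flag`` is one of ``eligible`` / ``ineligible`` / ``missing``.
    ``other_analgesics`` lists additional analgesics recorded in the episode
    (used by the single-analgesic comparator filter).
    """

    episode_id: str
    arm: str
    observations: tuple[PainObservation, ...]
    sex: int = 0
    age_years: float = 50.0
    trauma_class: int = 1
    gcs_flag: str = "eligible"
    under_18: bool = False
    pain_mild_none_baseline: bool = False
    trauma_ineligible: bool = False
    nonadherence: bool = False
    side_effect: bool = False
    discontinue_early: bool = False
    influence_entonox: bool = False
    influence_potency_1: bool = False
    influence_potency_2: bool = False
    influence_potency_3: bool = False
    other_analgesics: tuple[str, ...] = ()
    extra_admin_times_min: tuple[float, ...] = ()
    baseline_lead_time_min: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise EpisodeError(f"unknown arm label: {self.arm!r}")
        if not 1 <= int(self.trauma_class) <= 7:
            raise EpisodeError(f"trauma_class must be in 1..7: {self.trauma_class}")
        if self.gcs_flag not in ("eligible", "ineligible", "missing"):
            raise EpisodeError(f"unknown gcs_flag: {self.gcs_flag!r}")
        obs = tuple(sorted(self.observations, key=lambda o: o.time_min))
        object.__setattr__(self, "observations", obs)

    @property
    def gcs_ineligible_missing(self) -> bool:
        return self.gcs_flag != "eligible"

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(o.time_min for o in self.observations)

    @property
    def scores(self) -> tuple[int, ...]:
        return tuple(o.score for o in self.observations)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def baseline_score(self) -> int | None:
        """Score of the observation at time 0, if present."""
        for o in self.observations:
            if o.time_min == 0.0:
                return o.score
        return None

    def has_flag(self, name: str) -> bool:
        if name == "gcs_ineligible_missing":
            return self.gcs_ineligible_missing
        return bool(getattr(self, name))

    def any_ineligibility(self) -> bool:
        return any(self.has_flag(f) for f in INELIGIBILITY_FLAGS)


# ---------------------------------------------------------------------------
# baseline imputation

def impute_baseline(episode: Episode) -> Episode:
    """Assign the baseline score S0 at time 0.

    If a score exists exactly at time 0 it is the baseline (lead time 0).
    Otherwise the score taken nearest beforehand (latest time < 0) is
    reassigned to time 0, by protocol — it enters the model once, as the
    baseline — and the imputation lead time in minutes is recorded on the
    episode. Observations after time 0 are never altered.
    """
    pre = [o for o in episode.observations if o.time_min <= 0.0]
    if not pre:
        raise ImputationError(
            f"episode {episode.episode_id}: no observation at or before administration"
        )
    nearest = pre[-1]  # observations are sorted by time
    if nearest.time_min == 0.0:
        return replace(episode, baseline_lead_time_min=0.0)
    lead = -nearest.time_min
    obs = tuple(o for o in episode.observations if o is not nearest)
    obs += (PainObservation(0.0, nearest.score),)
    return replace(episode, observations=obs, baseline_lead_time_min=lead)


# ---------------------------------------------------------------------------
# inclusion filtering

@dataclass(frozen=True)
class FilterCriteria:
    """Configuration of the estimation-sample filters.

    ``period_of_effect_min`` maps each arm to the window (minutes from
    administration) during which later scores are attributed to the
    analgesic; 90 min by default for every arm, wide enough to cover the
    printed per-arm ranges of baseline-to-final durations.
    ``eligibility_exempt_arms`` lists arms whose licence-eligibility stages
    (adult / trauma / conscious / baseline pain) are recorded as flags rather
    than enforced — by default the methoxyflurane arm, matching the study
    design in which ineligible methoxyflurane uses stayed in the main sample.
    """

    period_of_effect_min: dict[str, float] = field(
        default_factory=lambda: {arm: 90.0 for arm in ARMS}
    )
    eligibility_exempt_arms: tuple[str, ...] = ("methoxyflurane",)
    single_analgesic_arms: tuple[str, ...] = COMPARATOR_ARMS
    flag_lead_time_over_min: float = 30.0

    def __post_init__(self) -> None:
        for arm in list(self.period_of_effect_min) + list(
            self.eligibility_exempt_arms
        ) + list(self.single_analgesic_arms):
            if arm not in ARMS:
                raise FilterConfigError(f"unknown arm label: {arm!r}")


FILTER_STAGES = (
    "adult",
    "trauma",
    "conscious",
    "baseline_pain",
    "score_sequence",
    "single_analgesic",
)


@dataclass
class AttritionReport:
    """Per-stage exclusion counts for one filtering pass."""

    n_input: int
    excluded: dict[str, int]
    retained_ids: tuple[str, ...]
    flagged_long_lead_ids: tuple[str, ...] = ()

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "excluded_by_stage": dict(self.excluded),
            "n_retained": self.n_retained,
            "flagged_long_lead_ids": list(self.flagged_long_lead_ids),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_text(self) -> str:
        lines = [f"Episodes in: {self.n_input}"]
        for stage in FILTER_STAGES:
            lines.append(f"  excluded at {stage:<16s}: {self.excluded.get(stage, 0)}")
        lines.append(f"Episodes retained: {self.n_retained}")
        return "\n".join(lines)


def _passes_stage(ep: Episode, stage: str, criteria: FilterCriteria) -> bool:
    exempt = ep.arm in criteria.eligibility_exempt_arms
    if stage == "adult":
        return exempt or (ep.age_years >= 18.0 and not ep.under_18)
    if stage == "trauma":
        return exempt or not ep.trauma_ineligible
    if stage == "conscious":
        return exempt or not ep.gcs_ineligible_missing
    if stage == "baseline_pain":
        if exempt:
            return True
        pre = [o for o in ep.observations if o.time_min <= 0.0]
        if not pre:
            return True  # no baseline to judge; the score-sequence stage excludes
        return is_moderate_to_severe(pre[-1].score) and not ep.pain_mild_none_baseline
    if stage == "score_sequence":
        if ep.n_obs < 2:
            return False
        first = ep.observations[0]
        if first.time_min > 0.0:
            return False
        window = criteria.period_of_effect_min.get(ep.arm, 90.0)
        return all(o.time_min <= window for o in ep.observations[1:])
    if stage == "single_analgesic":
        if ep.arm not in criteria.single_analgesic_arms:
            return True
        return len(ep.other_analgesics) == 0
    raise FilterConfigError(f"unknown filter stage: {stage}")


def apply_inclusion_filters(
    episodes: Iterable[Episode],
    criteria: FilterCriteria | None = None,
) -> tuple[list[Episode], AttritionReport]:
    """Apply the estimation-sample filters in their fixed order.

    Each episode is excluded at the *first* stage it fails, so stage counts
    are deterministic and sum with the retained count to the input count.
    Retained episodes whose baseline imputation lead time would exceed the
    configured threshold are flagged (not excluded).
    """
    criteria = criteria or FilterCriteria()
    episodes = list(episodes)
    excluded = {stage: 0 for stage in FILTER_STAGES}
    retained: list[Episode] = []
    long_lead: list[str] = []
    for ep in episodes:
        failed = None
        for stage in FILTER_STAGES:
            if not _passes_stage(ep, stage, criteria):
                failed = stage
                break
        if failed is not None:
            excluded[failed] += 1
            continue
        retained.append(ep)
        pre = [o for o in ep.observations if o.time_min <= 0.0]
        if pre and -pre[-1].time_min > criteria.flag_lead_time_over_min:
            long_lead.append(ep.episode_id)
    report = AttritionReport(
        n_input=len(episodes),
        excluded=excluded,
        retained_ids=tuple(ep.episode_id for ep in retained),
        flagged_long_lead_ids=tuple(long_lead),
    )
    return retained, report


def per_protocol_sample(
    episodes: Iterable[Episode],
) -> tuple[list[Episode], dict[str, int]]:
    """Remove episodes carrying any licence-ineligibility flag.

    Returns the per-protocol sample and a report of how many episodes and
    pain scores were removed. With no flags set this is the identity.
    """
    episodes = list(episodes)
    kept = [ep for ep in episodes if not ep.any_ineligibility()]
    removed = [ep for ep in episodes if ep.any_ineligibility()]
    report = {
        "episodes_removed": len(removed),
        "observations_removed": sum(ep.n_obs for ep in removed),
        "episodes_retained": len(kept),
    }
    return kept, report


# ---------------------------------------------------------------------------
# double-dose handling

def split_double_dose(
    episode: Episode,
    continuity_gap_min: float = 15.0,
    period_of_effect_min: float = 60.0,
) -> list[Episode]:
    """Split a twice-dosed episode into independent episodes when warranted.

    A second administration is *noncontinuous* with the first when it starts
    more than ``continuity_gap_min`` after the end of the first dose's period
    of effect; the two administrations are then treated as statistically
    independent episodes, each with its own baseline (times of the second
    re-referenced to its own administration). Otherwise the episode is kept
    merged. More than two administrations are unsupported.
    """
    extra = episode.extra_admin_times_min
    if len(extra) == 0:
        return [episode]
    if len(extra) > 1:
        raise EpisodeError(
            f"episode {episode.episode_id}: >2 administrations unsupported"
        )
    second = float(extra[0])
    if second <= period_of_effect_min + continuity_gap_min:
        return [replace(episode, extra_admin_times_min=())]
    first_obs = tuple(o for o in episode.observations if o.time_min < second)
    second_obs = tuple(
        PainObservation(o.time_min - second, o.score)
        for o in episode.observations
        if o.time_min >= second
    )
    # last pre-second-dose score doubles as the second episode's baseline
    if first_obs and not any(o.time_min <= 0 for o in second_obs):
        carry = first_obs[-1]
        second_obs = (PainObservation(carry.time_min - second, carry.score),) + second_obs
    ep1 = replace(
        episode,
        episode_id=f"{episode.episode_id}a",
        observations=first_obs,
        extra_admin_times_min=(),
    )
    ep2 = replace(
        episode,
        episode_id=f"{episode.episode_id}b",
        observations=second_obs,
        extra_admin_times_min=(),
    )
    return [ep1, ep2]


# ---------------------------------------------------------------------------
# long-format CSV interface

def episodes_to_frame(episodes: Sequence[Episode]) -> pd.DataFrame:
    """Long-format table, one row per pain observation."""
    rows = []
    for ep in episodes:
        for o in ep.observations:
            rows.append(
                {
                    "episode_id": ep.episode_id,
                    "arm": ep.arm,
                    "time_min": o.time_min,
                    "vnps": o.score,
                    "sex": ep.sex,
                    "age_years": ep.age_years,
                    "trauma_class": ep.trauma_class,
                    "gcs_flag": ep.gcs_flag,
                    **{f: int(getattr(ep, f)) for f in FLAG_COLUMNS},
                    "other_analgesics": ";".join(ep.other_analgesics),
                }
            )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_episodes(frame: pd.DataFrame) -> list[Episode]:
    missing = set(CSV_COLUMNS) - {"other_analgesics"} - set(frame.columns)
    if missing:
        raise EpisodeError(f"episode table missing columns: {sorted(missing)}")
    episodes = []
    for eid, g in frame.groupby("episode_id", sort=False):
        head = g.iloc[0]
        others = ()
        if "other_analgesics" in g.columns and isinstance(head["other_analgesics"], str):
            others = tuple(x for x in head["other_analgesics"].split(";") if x)
        episodes.append(
            Episode(
                episode_id=str(eid),
                arm=str(head["arm"]),
                observations=tuple(
                    PainObservation(float(r.time_min), int(r.vnps))
                    for r in g.itertuples()
                ),
                sex=int(head["sex"]),
                age_years=float(head["age_years"]),
                trauma_class=int(head["trauma_class"]),
                gcs_flag=str(head["gcs_flag"]),
                other_analgesics=others,
                **{f: bool(int(head[f])) for f in FLAG_COLUMNS},
            )
        )
    return episodes


def write_episodes_csv(episodes: Sequence[Episode], path) -> None:
    episodes_to_frame(episodes).to_csv(path, index=False)


def read_episodes_csv(path) -> list[Episode]:
    return frame_to_episodes(pd.read_csv(path, keep_default_na=False, na_values=[""]))
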