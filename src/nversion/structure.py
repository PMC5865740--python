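"""Health-state topology for a multi-cohort HIV care-engagement model.

The model tracks annual cohorts of people living with HIV through mutually
exclusive health states defined by untreated disease stage (CD4-based:
Asymptomatic >350, Intermediate 200-350, AIDS <200 cells/uL) crossed with
care-engagement status, plus antiretroviral therapy (ART) strata by
initiation stage and time on treatment, and two absorbing death states.

The default roster ships as package data (``data/hiv_policy_model.yaml``):
48 states grouped into 13 main states, with three policy revisions declared
as deltas on the baseline topology:

* ``RE_ENTRY`` -- patients lost to follow-up (LTFU) in the Intermediate or
  AIDS stages may return to care;
* ``UNIVERSAL_ART`` -- ART starts directly from any not-engaged stage,
  bypassing pre-ART care;
* ``GUIDELINE_ART`` -- new ART strata permit initiation from the
  Asymptomatic-Late stage, earlier than baseline but later than Universal.

The topology is pure data: no transition probabilities live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Stage",
    "CareStatus",
    "Revision",
    "HealthState",
    "ModelStructure",
    "ConfigurationError",
    "ValidationError",
    "load_default_config",
    "build_structure",
    "changed_cells",
]

ENTRY_WEIGHT_TOL = 1e-12


class Stage(str, Enum):
    """Disease-progression stratum of a health state."""

    ASYMPTOMATIC_EARLY = "ASYMPTOMATIC_EARLY"
    ASYMPTOMATIC_LATE = "ASYMPTOMATIC_LATE"
    INTERMEDIATE = "INTERMEDIATE"
    AIDS = "AIDS"
    ON_ART = "ON_ART"  # ART-experienced stratum; substratum carries initiation stage + duration
    DEAD_AIDS = "DEAD_AIDS"
    DEAD_OTHER = "DEAD_OTHER"


class CareStatus(str, Enum):
    NOT_ENGAGED = "NOT_ENGAGED"
    PRE_ART_CARE = "PRE_ART_CARE"
    ON_ART = "ON_ART"
    LTFU = "LTFU"
    DEAD = "DEAD"


class Revision(str, Enum):
    """Closed enumeration of the model revisions."""

    BASELINE = "BASELINE"
    RE_ENTRY = "RE_ENTRY"
    UNIVERSAL_ART = "UNIVERSAL_ART"
    GUIDELINE_ART = "GUIDELINE_ART"


#: (stage, care_status) combinations a structure may declare.
ALLOWED_COMBOS: frozenset[tuple[Stage, CareStatus]] = frozenset(
    [
        *(
            (stage, care)
            for stage in (
                Stage.ASYMPTOMATIC_EARLY,
                Stage.ASYMPTOMATIC_LATE,
                Stage.INTERMEDIATE,
                Stage.AIDS,
            )
            for care in (CareStatus.NOT_ENGAGED, CareStatus.PRE_ART_CARE, CareStatus.LTFU)
        ),
        (Stage.ON_ART, CareStatus.ON_ART),
        (Stage.ON_ART, CareStatus.LTFU),
        (Stage.DEAD_AIDS, CareStatus.DEAD),
        (Stage.DEAD_OTHER, CareStatus.DEAD),
    ]
)


class ConfigurationError(ValueError):
    """Raised for malformed or unknown structure configuration."""


class ValidationError(ValueError):
    """Raised when a structure violates its topological invariants."""


@dataclass(frozen=True)
class HealthState:
    """A single mutually exclusive health state.

    ``substratum`` subdivides a stage (e.g. ART duration year within an
    initiation stratum); ``main_group`` names the coarse state the compact
    model reports (13 groups in the default roster).
    """

    id: str
    stage: Stage
    care_status: CareStatus
    substratum: str | None = None
    main_group: str | None = None

    @property
    def is_dead(self) -> bool:
        return self.care_status is CareStatus.DEAD


@dataclass(frozen=True, eq=True)
class ModelStructure:
    """Validated health-state topology for one model revision.

    ``transitions`` are ordered (from_id, to_id) pairs permitted by the
    revision; self-loops are explicit so that probability rows can be fully
    stochastic.  ``entry_weights`` distributes each entering cohort over the
    entry states and must sum to one.
    """

    states: tuple[HealthState, ...]
    transitions: frozenset[tuple[str, str]]
    entry_weights: Mapping[str, float]
    revision: Revision

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_id", {s.id: s for s in self.states})

    # -- lookups ---------------------------------------------------------

    @property
    def state_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.states)

    def state(self, sid: str) -> HealthState:
        return self._by_id[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self._by_id

    @property
    def absorbing_states(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.states if s.is_dead)

    @property
    def main_groups(self) -> tuple[str, ...]:
        """Distinct main-state groups in declaration order."""
        seen: dict[str, None] = {}
        for s in self.states:
            if s.main_group is not None:
                seen.setdefault(s.main_group, None)
        return tuple(seen)

    def outgoing(self, sid: str) -> tuple[str, ...]:
        return tuple(t for (f, t) in sorted(self.transitions) if f == sid)

    def incoming(self, sid: str) -> tuple[str, ...]:
        return tuple(f for (f, t) in sorted(self.transitions) if t == sid)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check all topological invariants; raise :class:`ValidationError`.

        Checks: unique ids, allowed (stage, care) combinations, DEAD states
        have DEAD care status, transition endpoints declared, absorbing
        closure (dead states keep a self-loop and nothing else), every
        non-absorbing state has at least one exit, entry weights sum to one.
        """
        problems: list[str] = []
        ids = [s.id for s in self.states]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            problems.append(f"duplicate state ids: {dupes}")
        for s in self.states:
            if (s.stage, s.care_status) not in ALLOWED_COMBOS:
                problems.append(
                    f"state {s.id}: combination ({s.stage.value}, {s.care_status.value}) not allowed"
                )
            if s.stage in (Stage.DEAD_AIDS, Stage.DEAD_OTHER) and not s.is_dead:
                problems.append(f"state {s.id}: dead stage without DEAD care status")
        declared = set(ids)
        for f, t in sorted(self.transitions):
            if f not in declared or t not in declared:
                problems.append(f"transition ({f}, {t}) references undeclared state")
        out: dict[str, set[str]] = {i: set() for i in declared}
        for f, t in self.transitions:
            if f in out:
                out[f].add(t)
        for s in self.states:
            if s.is_dead:
                extra = out[s.id] - {s.id}
                if extra:
                    problems.append(
                        f"absorbing state {s.id} has outgoing transitions {sorted(extra)}"
                    )
                if s.id not in out[s.id]:
                    problems.append(f"absorbing state {s.id} lacks its self-loop")
            elif not out[s.id]:
                problems.append(f"non-absorbing state {s.id} has no outgoing transition")
        for sid in self.entry_weights:
            if sid not in declared:
                problems.append(f"entry state {sid} not declared")
        for sid, w in self.entry_weights.items():
            if w < 0:
                problems.append(f"entry weight for {sid} is negative")
        total = sum(self.entry_weights.values())
        if abs(total - 1.0) > ENTRY_WEIGHT_TOL:
            problems.append(f"entry weights sum to {total!r}, expected 1")
        if problems:
            raise ValidationError("; ".join(problems))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "revision": self.revision.value,
            "states": [
                {
                    "id": s.id,
                    "stage": s.stage.value,
                    "care_status": s.care_status.value,
                    "substratum": s.substratum,
                    "main_group": s.main_group,
                }
                for s in self.states
            ],
            "transitions": sorted(list(t) for t in self.transitions),
            "entry": {k: self.entry_weights[k] for k in sorted(self.entry_weights)},
        }

    def to_json(self) -> str:
        """Canonical JSON serialization (deterministic byte-for-byte)."""
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# configuration loading


def load_default_config() -> dict:
    """Load the shipped structure configuration (roster + revision deltas)."""
    text = resources.files("nversion.data").joinpath("hiv_policy_model.yaml").read_text()
    return yaml.safe_load(text)


def _parse_state(rec: Mapping) -> HealthState:
    try:
        return HealthState(
            id=str(rec["id"]),
            stage=Stage(rec["stage"]),
            care_status=CareStatus(rec["care_status"]),
            substratum=rec.get("substratum"),
            main_group=rec.get("main_group"),
        )
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"bad state record {rec!r}: {exc}") from exc


def build_structure(revision: Revision | str, config: Mapping | str | Path | None = None) -> ModelStructure:
    """Build and validate the :class:`ModelStructure` for one revision.

    Parameters
    ----------
    revision:
        One of the :class:`Revision` tokens (enum or string).
    config:
        Structure configuration: a mapping with keys ``states``,
        ``transitions``, ``entry`` and ``revisions`` (per-revision deltas), a
        path to such a YAML file, or ``None`` for the shipped default.
    """
    if isinstance(revision, str):
        try:
            revision = Revision(revision.upper())
        except ValueError as exc:
            raise ConfigurationError(f"unknown revision token {revision!r}") from exc
    if config is None:
        config = load_default_config()
    elif isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    for key in ("states", "transitions", "entry"):
        if key not in config:
            raise ConfigurationError(f"configuration missing required key {key!r}")

    states = [_parse_state(rec) for rec in config["states"]]
    transitions = {(str(f), str(t)) for f, t in config["transitions"]}
    entry = {str(k): float(v) for k, v in config["entry"].items()}

    if revision is not Revision.BASELINE:
        deltas = (config.get("revisions") or {}).get(revision.value)
        if deltas is None:
            raise ConfigurationError(
                f"configuration declares no deltas for revision {revision.value}"
            )
        states.extend(_parse_state(rec) for rec in deltas.get("add_states", []))
        transitions.update((str(f), str(t)) for f, t in deltas.get("add_transitions", []))
        for k, v in (deltas.get("entry") or {}).items():
            entry[str(k)] = float(v)

    structure = ModelStructure(
        states=tuple(states),
        transitions=frozenset(transitions),
        entry_weights=entry,
        revision=revision,
    )
    structure.validate()
    return structure


# ---------------------------------------------------------------------------
# revision diffing


def changed_cells(structure_old: ModelStructure, structure_new: ModelStructure, layout) -> set[tuple[str, int]]:
    """Compact-grid cells that are new or whose formula set changes.

    A state row changes when the state is new, its inflow set (incoming
    transitions) changes, or its entry weight changes; an aggregate row
    changes when its member set gains states absent from the old structure.
    Every cell of a changed row, across all years, is returned as a
    ``(row_label, year)`` address.  The count is the denominator for the
    originals-per-changed-cell error rate.
    """
    from .layout import GridLayout  # local import to avoid a module cycle

    if not isinstance(layout, GridLayout):
        raise TypeError("layout must be a GridLayout")
    labels = {r.label for r in layout.rows}
    missing = [s for s in structure_new.state_ids if s not in labels]
    if missing:
        raise ValueError(f"layout incompatible with new structure; missing rows {missing}")

    old_in: dict[str, set[str]] = {sid: set() for sid in structure_old.state_ids}
    for f, t in structure_old.transitions:
        old_in[t].add(f)
    new_in: dict[str, set[str]] = {sid: set() for sid in structure_new.state_ids}
    for f, t in structure_new.transitions:
        new_in[t].add(f)

    changed_rows: set[str] = set()
    for row in layout.rows:
        if row.kind == "state":
            sid = row.label
            if sid not in structure_old:
                changed_rows.add(sid)
            elif new_in.get(sid, set()) != old_in.get(sid, set()):
                changed_rows.add(sid)
            elif structure_old.entry_weights.get(sid, 0.0) != structure_new.entry_weights.get(sid, 0.0):
                changed_rows.add(sid)
        elif row.kind == "aggregate":
            if any(m not in structure_old for m in row.members):
                changed_rows.add(row.label)

    return {(label, year) for label in changed_rows for year in layout.years}
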