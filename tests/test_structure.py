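"""Topology: default roster, revision deltas, validation, changed cells."""

import pytest

from nversion.layout import default_layout
from nversion.structure import (
    CareStatus,
    ConfigurationError,
    HealthState,
    ModelStructure,
    Revision,
    Stage,
    ValidationError,
    build_structure,
    changed_cells,
    load_default_config,
)

from conftest import chain_structure


def test_default_roster_has_48_states_in_13_main_groups(baseline_structure):
    assert len(baseline_structure.state_ids) == 48
    assert len(baseline_structure.main_groups) == 13


@pytest.mark.parametrize("revision", ["BASELINE", "RE_ENTRY", "UNIVERSAL_ART", "GUIDELINE_ART"])
def test_every_revision_validates(revision):
    structure = build_structure(revision)
    structure.validate()  # must not raise
    assert abs(sum(structure.entry_weights.values()) - 1.0) <= 1e-12


def test_revision_topology_is_monotone(baseline_structure):
    re_entry = build_structure("RE_ENTRY")
    universal = build_structure("UNIVERSAL_ART")
    guideline = build_structure("GUIDELINE_ART")
    assert baseline_structure.transitions <= re_entry.transitions
    assert baseline_structure.transitions <= universal.transitions
    assert set(baseline_structure.state_ids) <= set(guideline.state_ids)
    assert baseline_structure.transitions <= guideline.transitions


def test_re_entry_adds_only_return_to_care_edges(baseline_structure):
    """The re-entry revision adds exactly transitions from LTFU states in
    the Intermediate/AIDS strata back to in-care states, and the baseline
    has no LTFU-to-care edge at all."""
    re_entry = build_structure("RE_ENTRY")
    added = re_entry.transitions - baseline_structure.transitions
    assert added
    in_care = (CareStatus.PRE_ART_CARE, CareStatus.ON_ART)
    for frm, to in added:
        src, dst = re_entry.state(frm), re_entry.state(to)
        assert src.care_status is CareStatus.LTFU
        assert dst.care_status in in_care
        # LTFU either in the Intermediate/AIDS untreated stages or in ART
        # strata initiated at those stages
        if src.stage is Stage.ON_ART:
            assert "init=INT" in src.substratum or "init=AIDS" in src.substratum
        else:
            assert src.stage in (Stage.INTERMEDIATE, Stage.AIDS)
    for frm, to in baseline_structure.transitions:
        src, dst = baseline_structure.state(frm), baseline_structure.state(to)
        assert not (
            src.care_status is CareStatus.LTFU and dst.care_status in in_care
        ), f"baseline has a re-entry edge {frm}->{to}"


def test_universal_adds_direct_art_start_from_every_stage(baseline_structure):
    universal = build_structure("UNIVERSAL_ART")
    assert set(universal.state_ids) == set(baseline_structure.state_ids)
    added = universal.transitions - baseline_structure.transitions
    stages_with_direct_start = set()
    for frm, to in added:
        src, dst = universal.state(frm), universal.state(to)
        assert src.care_status is CareStatus.NOT_ENGAGED
        assert dst.care_status is CareStatus.ON_ART
        stages_with_direct_start.add(src.stage)
    assert stages_with_direct_start == {
        Stage.ASYMPTOMATIC_EARLY,
        Stage.ASYMPTOMATIC_LATE,
        Stage.INTERMEDIATE,
        Stage.AIDS,
    }


def test_guideline_adds_asymptomatic_late_initiation_strata(baseline_structure):
    guideline = build_structure("GUIDELINE_ART")
    new_states = set(guideline.state_ids) - set(baseline_structure.state_ids)
    assert new_states
    assert all(guideline.state(s).stage is Stage.ON_ART for s in new_states)
    assert all("init=AL" in guideline.state(s).substratum for s in new_states)
    assert ("AL_PRE", "ART_AL_Y1") in guideline.transitions


def test_same_config_builds_bitwise_identical_structure():
    a = build_structure("GUIDELINE_ART")
    b = build_structure("GUIDELINE_ART")
    assert a.to_json() == b.to_json()


def test_unknown_revision_token_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        build_structure("IMMEDIATE_ART")


def test_validation_lists_offending_transitions():
    config = load_default_config()
    config["transitions"].append(["AE_NE", "NO_SUCH_STATE"])
    with pytest.raises(ValidationError, match="NO_SUCH_STATE"):
        build_structure("BASELINE", config)


def test_entry_weights_must_sum_to_one():
    config = load_default_config()
    config["entry"]["AE_NE"] = 0.9
    with pytest.raises(ValidationError, match="entry weights"):
        build_structure("BASELINE", config)


def test_absorbing_states_may_not_leak():
    structure = chain_structure(2)
    bad = ModelStructure(
        states=structure.states,
        transitions=structure.transitions | {("DEAD", "S0")},
        entry_weights=structure.entry_weights,
        revision=Revision.BASELINE,
    )
    with pytest.raises(ValidationError, match="absorbing"):
        bad.validate()


# ---------------------------------------------------------------------------
# changed cells


def test_identical_structures_change_no_cells(baseline_structure):
    layout = default_layout(baseline_structure, range(2009, 2024))
    assert changed_cells(baseline_structure, baseline_structure, layout) == set()


def test_added_state_changes_its_whole_row():
    """A toy revision adding one state changes exactly that state's row
    (enumerable by hand: 3 years -> 3 cells) plus any aggregate rows that
    gained the state."""
    old = chain_structure(2)
    new_states = old.states[:-1] + (
        HealthState("S_NEW", Stage.AIDS, CareStatus.NOT_ENGAGED),
        old.states[-1],
    )
    new = ModelStructure(
        states=new_states,
        transitions=old.transitions | {("S_NEW", "S_NEW"), ("S_NEW", "DEAD")},
        entry_weights=old.entry_weights,
        revision=Revision.GUIDELINE_ART,
    )
    new.validate()
    years = (2009, 2010, 2011)
    layout = default_layout(new, years)
    changed = changed_cells(old, new, layout)
    state_changed = {(label, y) for (label, y) in changed if label == "S_NEW"}
    assert state_changed == {("S_NEW", y) for y in years}
    # remaining changed cells: aggregate rows that gained S_NEW, plus DEAD,
    # whose inflow formula gains the new state's death transition
    agg_rows = {r.label for r in layout.rows if r.kind == "aggregate" and "S_NEW" in r.members}
    assert {label for (label, y) in changed} - {"S_NEW"} == agg_rows | {"DEAD"}


def test_re_entry_changed_cells_are_rows_with_new_inflows(baseline_structure):
    re_entry = build_structure("RE_ENTRY")
    years = range(2009, 2024)
    layout = default_layout(re_entry, years)
    changed = changed_cells(baseline_structure, re_entry, layout)
    rows = {label for (label, _) in changed}
    # states gaining inflows under re-entry: the re-engagement targets
    assert rows == {"INT_PRE", "AIDS_PRE", "ART_INT_Y1", "ART_AIDS_Y1"}
    assert len(changed) == len(rows) * 15


def test_changed_cells_rejects_incompatible_layout(baseline_structure):
    guideline = build_structure("GUIDELINE_ART")
    layout = default_layout(baseline_structure, range(2009, 2024))
    with pytest.raises(ValueError, match="missing rows"):
        changed_cells(baseline_structure, guideline, layout)
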