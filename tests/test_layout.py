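"""Block sorting, realignment, grouping, flows, highlighting."""

import random

import pytest

from cohortflow.layout import (
    MISSING_GROUP,
    build_flowsets,
    compute_flows,
    group_block,
    highlight_selection,
    layout_state_to_dict,
    realign_all,
    sort_block,
    sort_block_multi,
)
from cohortflow.model import derive_blocks
from cohortflow.synth import SyntheticCohortConfig, generate_synthetic_cohort

from conftest import make_feature


def lexicographic_oracle(order, key_fn):
    """Stable lexicographic sort with prior order as final tiebreaker."""
    return sorted(order, key=key_fn)


class TestSortBlock:
    def test_stable_sort_by_grade(self, small_cohort):
        grid = derive_blocks(small_cohort, ["grade"])
        b = sort_block(grid.blocks[0], small_cohort.features["grade"])
        # grades at tp0: P1=II P2=II P3=III P4=II; ties keep prior order
        assert b.order == ["P1", "P2", "P4", "P3"]
        assert b.primary_feature == "grade"

    def test_resorting_sorted_block_is_idempotent(self, small_cohort):
        grid = derive_blocks(small_cohort, ["grade"])
        once = sort_block(grid.blocks[0], small_cohort.features["grade"])
        twice = sort_block(once, small_cohort.features["grade"])
        assert once.order == twice.order

    def test_missing_and_gap_sort_last(self, small_cohort):
        feat = make_feature(
            "partial", "continuous",
            {"P2_S0": 1.0, "P4_S0": 2.0, "P1_S0": None, "P3_S0": 5.0},
        )
        small_cohort.add_feature(feat)
        grid = derive_blocks(small_cohort, ["partial"])
        b = sort_block(grid.blocks[0], feat, "desc")
        assert b.order == ["P3", "P4", "P2", "P1"]  # missing P1 last even desc

    def test_all_missing_leaves_order_unchanged(self, small_cohort):
        feat = make_feature("empty", "continuous", {})
        small_cohort.add_feature(feat)
        grid = derive_blocks(small_cohort, ["empty"])
        b = sort_block(grid.blocks[0], feat)
        assert b.order == grid.blocks[0].order

    def test_undisplayed_feature_rejected(self, small_cohort):
        grid = derive_blocks(small_cohort, ["grade"])
        with pytest.raises(KeyError, match="not displayed"):
            sort_block(grid.blocks[0], small_cohort.features["MGMT"])


class TestSortBlockMulti:
    def test_worked_example(self, small_cohort):
        f1 = make_feature("f1", "ordinal",
                          {"P1_S0": "III", "P2_S0": "II", "P3_S0": "II", "P4_S0": "III"},
                          domain=["II", "III"])
        f2 = make_feature("f2", "continuous",
                          {"P1_S0": 5.0, "P2_S0": 3.0, "P3_S0": 9.0, "P4_S0": 1.0})
        small_cohort.add_feature(f1)
        small_cohort.add_feature(f2)
        grid = derive_blocks(small_cohort, ["f1", "f2"])
        b = sort_block_multi(grid.blocks[0], [f1, f2], ["asc", "asc"])
        assert b.order == ["P2", "P3", "P4", "P1"]

    def test_single_key_equals_sort_block(self, small_cohort):
        grid = derive_blocks(small_cohort, ["grade"])
        feat = small_cohort.features["grade"]
        assert sort_block_multi(grid.blocks[0], [feat], ["asc"]).order == \
            sort_block(grid.blocks[0], feat).order

    def test_length_mismatch_rejected(self, small_cohort):
        grid = derive_blocks(small_cohort, ["grade"])
        with pytest.raises(ValueError, match="directions"):
            sort_block_multi(grid.blocks[0], [small_cohort.features["grade"]], [])

    def test_matches_bruteforce_on_random_instances(self, small_cohort):
        """Repeated stable sorts == one-shot lexicographic sort oracle."""
        rng = random.Random(42)
        for _ in range(60):
            n = rng.randint(2, 12)
            n_keys = rng.randint(1, 4)
            from cohortflow.model import Cohort, PatientRecord
            cohort = Cohort(patients=[
                PatientRecord(f"P{i}", [(f"P{i}_S0", 0)]) for i in range(n)
            ])
            feats = []
            for k in range(n_keys):
                vals = {f"P{i}_S0": float(rng.randint(0, 3)) for i in range(n)}
                f = make_feature(f"k{k}", "continuous", vals)
                cohort.add_feature(f)
                feats.append(f)
            dirs = [rng.choice(["asc", "desc"]) for _ in range(n_keys)]
            grid = derive_blocks(cohort, [f.feature_id for f in feats])
            got = sort_block_multi(grid.blocks[0], feats, dirs).order

            prior_pos = {p: i for i, p in enumerate(grid.blocks[0].order)}

            def key(pid):
                parts = []
                for f, d in zip(feats, dirs):
                    v = f.values[f"{pid}_S0"]
                    parts.append(v if d == "asc" else -v)
                parts.append(prior_pos[pid])
                return tuple(parts)

            assert got == lexicographic_oracle(grid.blocks[0].order, key)


class TestRealign:
    def test_propagated_order_eliminates_crossings(self, small_cohort):
        grid = derive_blocks(small_cohort, ["grade"])
        grid.blocks[1] = sort_block(grid.blocks[1], small_cohort.features["grade"])
        blocks = realign_all(grid.blocks, 1)
        fs = compute_flows(blocks[0], blocks[1])
        positions = [(a[1], b[1]) for _, a, b in fs.lines]
        crossings = sum(
            1
            for i in range(len(positions))
            for j in range(i + 1, len(positions))
            if (positions[i][0] - positions[j][0]) * (positions[i][1] - positions[j][1]) < 0
        )
        assert crossings == 0

    def test_idempotent(self, small_cohort):
        grid = derive_blocks(small_cohort, ["grade"])
        grid.blocks[1] = sort_block(grid.blocks[1], small_cohort.features["grade"])
        once = realign_all(grid.blocks, 1)
        twice = realign_all(once, 1)
        assert [b.order for b in once] == [b.order for b in twice]

    def test_patients_absent_from_reference_appended(self, ragged_cohort):
        grid = derive_blocks(ragged_cohort, ["score"])
        # sort last block (only C present, but order covers all columns)
        blocks = realign_all(grid.blocks, 3)
        assert set(blocks[0].order) == {"A", "B", "C"}

    def test_grouped_reference_rejected(self, small_cohort):
        grid = derive_blocks(small_cohort, ["grade"])
        grid.blocks[0].grouped = True
        with pytest.raises(ValueError, match="grouped"):
            realign_all(grid.blocks, 0)


class TestGroupBlock:
    def test_mgmt_proportions(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT", "grade", "mut_count"])
        gb = group_block(grid.blocks[0], small_cohort.features["MGMT"],
                         small_cohort.features)
        assert gb.group_sizes() == {"meth": 3, "unmeth": 1}
        # group order follows the domain order
        assert [g for g, _ in gb.groups] == ["meth", "unmeth"]

    def test_continuous_primary_rejected_citing_binning(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT", "mut_count"])
        with pytest.raises(ValueError, match="bin"):
            group_block(grid.blocks[0], small_cohort.features["mut_count"],
                        small_cohort.features)

    def test_five_number_summary(self, small_cohort):
        # tp0 mut_count within meth group {P1,P3,P4}: 40, 30, 80
        grid = derive_blocks(small_cohort, ["MGMT", "mut_count"])
        gb = group_block(grid.blocks[0], small_cohort.features["MGMT"],
                         small_cohort.features)
        summ = gb.nested_summaries["meth"]["mut_count"]
        assert summ["five_number"] == (30.0, 35.0, 40.0, 60.0, 80.0)

    def test_nested_categorical_counts_sum_to_group_size(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT", "grade"])
        gb = group_block(grid.blocks[1], small_cohort.features["MGMT"],
                         small_cohort.features)
        for g, pids in gb.groups:
            assert sum(gb.nested_summaries[g]["grade"].values()) == len(pids)

    def test_missing_primary_forms_trailing_group(self, small_cohort):
        feat = make_feature("sparse", "categorical",
                            {"P1_S0": "x", "P2_S0": None, "P3_S0": "x", "P4_S0": None},
                            domain=["x"])
        small_cohort.add_feature(feat)
        grid = derive_blocks(small_cohort, ["sparse"])
        gb = group_block(grid.blocks[0], feat, small_cohort.features)
        assert [g for g, _ in gb.groups] == ["x", MISSING_GROUP]
        assert gb.group_sizes()[MISSING_GROUP] == 2

    def test_ungrouping_restores_order(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT"])
        before = list(grid.blocks[0].order)
        group_block(grid.blocks[0], small_cohort.features["MGMT"], small_cohort.features)
        assert grid.blocks[0].order == before  # grouping never mutates the block


class TestComputeFlows:
    def test_worked_transition_example(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT"])
        feats = small_cohort.features
        g0 = group_block(grid.blocks[0], feats["MGMT"], feats)
        g1 = group_block(grid.blocks[1], feats["MGMT"], feats)
        fs = compute_flows(g0, g1)
        assert fs.mode == "flows"
        assert fs.flow_counts() == {
            ("meth", "meth"): 2, ("meth", "unmeth"): 1, ("unmeth", "unmeth"): 1,
        }

    def test_identical_ungrouped_order_gives_parallel_lines(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT"])
        fs = compute_flows(grid.blocks[0], grid.blocks[1])
        assert fs.mode == "lines"
        assert all(a == b for _, (_, a), (_, b) in fs.lines)

    def test_gap_patient_excluded_and_counted_as_exit(self, ragged_cohort):
        grid = derive_blocks(ragged_cohort, ["score"])
        fs = compute_flows(grid.blocks[1], grid.blocks[2])
        assert {p for p, _, _ in fs.lines} == {"B", "C"}
        assert fs.exits == ["A"]

    def test_mixed_mode_lines_carry_group_anchor(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT"])
        feats = small_cohort.features
        g1 = group_block(grid.blocks[1], feats["MGMT"], feats)
        fs = compute_flows(grid.blocks[0], g1)
        assert fs.mode == "mixed"
        kinds = {(a[0], b[0]) for _, a, b in fs.lines}
        assert kinds == {("pos", "group")}

    def test_non_adjacent_blocks_rejected(self, ragged_cohort):
        grid = derive_blocks(ragged_cohort, ["score"])
        with pytest.raises(ValueError, match="not adjacent"):
            compute_flows(grid.blocks[0], grid.blocks[2])

    @pytest.mark.parametrize("seed", range(12))
    def test_flow_conservation_on_random_cohorts(self, seed):
        cfg = SyntheticCohortConfig(n_patients=12, seed=seed)
        cohort, _ = generate_synthetic_cohort(cfg)
        feats = cohort.features
        grid = derive_blocks(cohort, ["TUMOR_GRADE"])
        g0 = group_block(grid.blocks[0], feats["TUMOR_GRADE"], feats)
        g1 = group_block(grid.blocks[1], feats["TUMOR_GRADE"], feats)
        fs = compute_flows(g0, g1)
        shared = set(g0.patients()) & set(g1.patients())
        for g, pids in g0.groups:
            out = sum(len(v) for (ga, _), v in fs.flows.items() if ga == g)
            assert out == len(set(pids) & shared)
        for g, pids in g1.groups:
            inc = sum(len(v) for (_, gb), v in fs.flows.items() if gb == g)
            assert inc == len(set(pids) & shared)


class TestHighlightAndSerialization:
    def test_single_patient_selection_flags_one_line(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT"])
        fs = compute_flows(grid.blocks[0], grid.blocks[1])
        (fs2,), _ = highlight_selection([fs], [], ["P2"], small_cohort.patient_ids)
        assert fs2.highlight == {"P2"}

    def test_partial_flow_selection_counts(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT"])
        feats = small_cohort.features
        g0 = group_block(grid.blocks[0], feats["MGMT"], feats)
        (g0b,) = highlight_selection([], [g0], ["P1", "P3"], small_cohort.patient_ids)[1]
        assert g0b.selected_counts == {"meth": 2, "unmeth": 0}

    def test_empty_selection_zero_annotations(self, small_cohort):
        grid = derive_blocks(small_cohort, ["MGMT"])
        fs = compute_flows(grid.blocks[0], grid.blocks[1])
        (fs2,), _ = highlight_selection([fs], [], [], small_cohort.patient_ids)
        assert fs2.highlight == set()

    def test_unknown_patient_rejected(self, small_cohort):
        with pytest.raises(KeyError, match="unknown patient"):
            highlight_selection([], [], ["NOPE"], small_cohort.patient_ids)

    def test_layout_state_serializes_to_json(self, small_cohort):
        import json
        grid = derive_blocks(small_cohort, ["MGMT"])
        feats = small_cohort.features
        g0 = group_block(grid.blocks[0], feats["MGMT"], feats)
        g1 = group_block(grid.blocks[1], feats["MGMT"], feats)
        fs = compute_flows(g0, g1)
        state = layout_state_to_dict(grid.blocks, [g0, g1], [fs])
        assert json.loads(json.dumps(state)) == state

    def test_build_flowsets_bridges_ungrouped_event_block(self, small_cohort):
        from cohortflow.model import event_attribute_feature
        agent = event_attribute_feature(small_cohort, "TREATMENT", "AGENT")
        grid = derive_blocks(small_cohort, ["MGMT"], include_events=True,
                             event_features=[agent.feature_id])
        flowsets = build_flowsets(grid.blocks)
        # single ungrouped event block bridged: one flowset tp0 -> tp1
        assert len(flowsets) == 1
        assert flowsets[0].between == (grid.blocks[0].index, grid.blocks[2].index)
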