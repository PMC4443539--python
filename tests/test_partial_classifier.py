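"""Split-chain detection, model projection, and the bounded/unbounded rule."""

import numpy as np
import pytest

from partialdom.annotation_core import DomainAnnotation, FamilyModel, coverage
from partialdom.partial_classifier import (
    BOUNDED,
    SPLIT,
    UNBOUNDED,
    ClassifierParams,
    build_chains,
    classify_all,
    classify_bounded_unbounded,
    classify_split,
    project_full_model,
)
from partialdom.synthetic_data import SimulationConfig, simulate_dataset
from conftest import make_dataset


def _cov_map(annotations, families):
    fams = {f.family_id: f for f in families}
    return {a.key: coverage(a, fams[a.family_id]) for a in annotations}


class TestChains:
    FAM = FamilyModel("PF01544", 292)

    def test_consistent_pieces_merge_with_small_overlap(self):
        a1 = DomainAnnotation("s", "PF01544", 1, 400, 1, 192)
        a2 = DomainAnnotation("s", "PF01544", 401, 530, 190, 292)
        chains = build_chains([a1, a2], {"PF01544": None}, overlap_tolerance=10)
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_tandem_repeat_stays_separate(self):
        # downstream copy restarts the model: orientation inconsistent
        a1 = DomainAnnotation("s", "PF01544", 1, 400, 1, 192)
        a2 = DomainAnnotation("s", "PF01544", 401, 530, 1, 103)
        chains = build_chains([a1, a2], {"PF01544": None}, overlap_tolerance=10)
        assert sorted(len(c) for c in chains) == [1, 1]

    def test_overlap_beyond_tolerance_breaks_chain(self):
        a1 = DomainAnnotation("s", "PF01544", 1, 400, 1, 192)
        a2 = DomainAnnotation("s", "PF01544", 401, 530, 150, 292)
        chains = build_chains([a1, a2], {"PF01544": None}, overlap_tolerance=10)
        assert sorted(len(c) for c in chains) == [1, 1]

    def test_clan_membership_counts_as_homologous(self):
        clan_map = {"A": "CL1", "B": "CL1", "C": None}
        a1 = DomainAnnotation("s", "A", 1, 100, 1, 100)
        a2 = DomainAnnotation("s", "B", 101, 200, 120, 220)
        chains = build_chains([a1, a2], clan_map, overlap_tolerance=10)
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_singleton(self):
        a1 = DomainAnnotation("s", "PF01544", 1, 100, 1, 100)
        assert build_chains([a1], {"PF01544": None}, 10) == [[a1]]

    def test_order_independence(self, rng):
        clan_map = {"A": None}
        anns = [
            DomainAnnotation("s", "A", 1 + 120 * i, 100 + 120 * i, 1 + 80 * i, 80 + 80 * i)
            for i in range(5)
        ]
        ref = build_chains(anns, clan_map, 10)
        for _ in range(20):
            shuffled = [anns[i] for i in rng.permutation(5)]
            assert build_chains(shuffled, clan_map, 10) == ref


class TestSplit:
    def test_short_member_of_two_piece_chain_is_split(self):
        fam = FamilyModel("PF01544", 292)
        a1 = DomainAnnotation("s", "PF01544", 1, 400, 1, 192)
        a2 = DomainAnnotation("s", "PF01544", 401, 530, 190, 292)  # 103 states
        chains = build_chains([a1, a2], {"PF01544": None}, 10)
        labels = classify_split(chains, _cov_map([a1, a2], [fam]))
        assert a2.key in labels and a1.key not in labels

    def test_three_piece_chain_all_short_members_split(self):
        fam = FamilyModel("PF01544", 292)
        anns = [
            DomainAnnotation("s", "PF01544", 1, 300, 1, 100),
            DomainAnnotation("s", "PF01544", 500, 800, 98, 200),
            DomainAnnotation("s", "PF01544", 900, 1200, 198, 292),
        ]
        chains = build_chains(anns, {"PF01544": None}, 10)
        assert len(chains) == 1
        labels = classify_split(chains, _cov_map(anns, [fam]))
        assert set(labels) == {a.key for a in anns}

    def test_singleton_never_split(self):
        fam = FamilyModel("PF01544", 292)
        a = DomainAnnotation("s", "PF01544", 1, 100, 1, 100)
        assert classify_split([[a]], _cov_map([a], [fam])) == {}


class TestProjection:
    def test_interior_projection_arithmetic(self):
        fam = FamilyModel("F", 292)
        ann = DomainAnnotation("s", "F", 200, 340, 90, 230)
        proj = project_full_model(ann, fam, seq_length=500)
        assert (proj.proj_start, proj.proj_end) == (111, 402)
        assert not proj.clipped_left and not proj.clipped_right

    def test_clip_at_n_terminus(self):
        fam = FamilyModel("F", 292)
        ann = DomainAnnotation("s", "F", 50, 200, 90, 240)
        proj = project_full_model(ann, fam, seq_length=500)
        assert proj.proj_start == 1 and proj.clipped_left

    def test_full_model_projection_is_identity(self):
        fam = FamilyModel("F", 292)
        ann = DomainAnnotation("s", "F", 30, 321, 1, 292)
        proj = project_full_model(ann, fam, seq_length=400)
        assert (proj.proj_start, proj.proj_end) == (30, 321)


class TestBoundedUnbounded:
    def _classify(self, ann, others, fam, seq_length, **kw):
        proj = project_full_model(ann, fam, seq_length)
        clan_map = kw.pop("clan_map", {fam.family_id: None})
        return classify_bounded_unbounded(
            ann, proj, [ann] + others, clan_map, fam, seq_length, **kw
        )

    def test_short_protein_bounds_the_tail_partial(self):
        # 141 residues cannot hold ~90% of a 292-state model
        fam = FamilyModel("PF01544", 292)
        ann = DomainAnnotation("Q7U9V6", "PF01544", 10, 135, 167, 292)
        category, evidence = self._classify(ann, [], fam, seq_length=141)
        assert category == BOUNDED
        assert "terminus" in evidence

    def test_non_homologous_neighbor_bounds_the_partial(self):
        fam = FamilyModel("PF00183", 700)
        clan_map = {"PF00183": None, "PF08454": None}
        ann = DomainAnnotation("E9GP80", "PF00183", 500, 790, 400, 700)
        blocker = DomainAnnotation("E9GP80", "PF08454", 100, 480, 1, 380)
        category, evidence = self._classify(
            ann, [blocker], fam, seq_length=900, clan_map=clan_map
        )
        assert category == BOUNDED
        assert "PF08454" in evidence

    def test_homologous_neighbor_does_not_bound(self):
        fam = FamilyModel("A", 292)
        clan_map = {"A": "CL1", "B": "CL1"}
        ann = DomainAnnotation("s", "A", 500, 640, 150, 292)
        same_clan = DomainAnnotation("s", "B", 100, 480, 1, 200)
        category, _ = self._classify(
            ann, [same_clan], fam, seq_length=900, clan_map=clan_map
        )
        assert category == UNBOUNDED

    def test_room_everywhere_is_unbounded(self):
        fam = FamilyModel("F", 292)
        ann = DomainAnnotation("s", "F", 400, 530, 160, 292)
        category, _ = self._classify(ann, [], fam, seq_length=900)
        assert category == UNBOUNDED

    def test_category_is_monotone_in_slack(self):
        # loosening the free-span requirement can only turn bounded calls
        # into unbounded ones, never the reverse
        fam = FamilyModel("F", 300)
        ann = DomainAnnotation("s", "F", 10, 130, 180, 300)
        seq_length = 282  # free span 282 residues: 0.94 * model_length
        seen_unbounded = False
        for slack in (0.0, 0.03, 0.05, 0.1, 0.2):
            category, _ = self._classify(ann, [], fam, seq_length, slack=slack)
            if seen_unbounded:
                assert category == UNBOUNDED
            seen_unbounded = seen_unbounded or category == UNBOUNDED
        assert self._classify(ann, [], fam, seq_length, slack=0.0)[0] == BOUNDED
        assert self._classify(ann, [], fam, seq_length, slack=0.1)[0] == UNBOUNDED


class TestClassifyAll:
    def test_partition_and_exact_recovery_on_noiseless_plants(self):
        cfg = SimulationConfig(
            seed=11,
            n_families=3,
            members_per_family=20,
            n_split=4,
            n_bounded_terminus=2,
            n_bounded_neighbor=3,
            n_unbounded=5,
            with_residues=False,
        )
        sim = simulate_dataset(cfg)
        result = classify_all(sim.dataset)
        truth = sim.truth_by_key()
        expected = {k: v for k, v in truth.items() if v in (SPLIT, BOUNDED, UNBOUNDED)}
        got = {c.annotation.key: c.category for c in result.classifications}
        assert got == expected
        tally = result.domain_tally()
        assert tally["split"] + tally["bounded"] + tally["unbounded"] == tally["total"]

    def test_no_partials_gives_empty_classification(self):
        ds = make_dataset(
            [("F", 200)],
            [("s", 400)],
            [("s", "F", 50, 249, 1, 200)],
        )
        result = classify_all(ds)
        assert result.classifications == []
        assert result.domain_tally()["total"] == 0

    def test_sequence_counted_once_per_category(self):
        # one sequence with a split pair (one short piece) and a bounded partial
        ds = make_dataset(
            [("A", 300), ("B", 300), ("X", 400)],
            [("s", 900)],
            [
                ("s", "A", 1, 200, 1, 200),
                ("s", "A", 201, 300, 199, 300),  # 102 states: split partial
                ("s", "X", 320, 700, 1, 400),    # non-homologous wall
                ("s", "B", 710, 830, 180, 300),  # 121 states, hemmed in
            ],
        )
        result = classify_all(ds)
        dom = result.domain_tally()
        seq = result.sequence_tally()
        assert dom["split"] == 1 and dom["bounded"] == 1
        assert seq["split"] == 1 and seq["bounded"] == 1 and seq["total"] == 1

    def test_partition_property_over_random_datasets(self):
        for seed in range(25):
            cfg = SimulationConfig(
                seed=seed,
                n_families=2,
                members_per_family=10,
                n_split=2,
                n_bounded_terminus=1,
                n_bounded_neighbor=1,
                n_unbounded=2,
                with_residues=False,
            )
            sim = simulate_dataset(cfg)
            result = classify_all(sim.dataset)
            fams = sim.dataset.families
            partials = [
                a
                for a in sim.dataset.annotations
                if (a.model_end - a.model_start + 1) < 0.5 * fams[a.family_id].model_length
            ]
            assert len(result.classifications) == len(partials)
            assert {c.annotation.key for c in result.classifications} == {
                a.key for a in partials
            }

    def test_shuffled_annotation_order_gives_same_result(self, rng):
        cfg = SimulationConfig(seed=3, n_families=2, members_per_family=12, with_residues=False)
        sim = simulate_dataset(cfg)
        ref = {
            c.annotation.key: c.category
            for c in classify_all(sim.dataset).classifications
        }
        for _ in range(5):
            anns = list(sim.dataset.annotations)
            sim.dataset.annotations = [anns[i] for i in rng.permutation(len(anns))]
            got = {
                c.annotation.key: c.category
                for c in classify_all(sim.dataset).classifications
            }
            assert got == ref
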