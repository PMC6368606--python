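"""Local alignment, greedy threshold clustering, and the 90/60/30 cascade."""

import random

import numpy as np
import pytest

from springdiv.exceptions import (
    ConsistencyError,
    InvalidInputError,
    InvalidParameterError,
)
from springdiv.seqcluster import (
    AMINO_ACIDS,
    ProteinRecord,
    align_local,
    assert_threshold_soundness,
    cascade,
    cluster_at,
    family_abundance,
    filter_by_length,
)
from springdiv.synthetic import mutate_to_identity

from conftest import make_records
from oracles import sw_score

PANEL = AMINO_ACIDS  # 20 distinct residues, length 20


def random_protein(rng, length=120):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


class TestAlignLocal:
    def test_self_alignment_is_perfect(self):
        stats = align_local(PANEL, PANEL)
        assert stats.identity == 1.0
        assert stats.coverage_short == 1.0

    def test_single_substitution_identity(self):
        mutated = PANEL[:10] + "A" + PANEL[11:]  # L -> A at position 10
        stats = align_local(PANEL, mutated)
        assert stats.identity == pytest.approx(0.95)
        assert stats.coverage_short == 1.0
        assert stats.score == pytest.approx(sw_score(PANEL, mutated))

    def test_disjoint_alphabets_have_no_alignment(self):
        stats = align_local("A" * 20, "W" * 20)
        assert stats.identity == 0.0
        assert stats.coverage_short == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            align_local("", PANEL)

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_dynamic_programming_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, 40)
        b = mutate_to_identity(a, 0.7, rng) if seed % 2 else random_protein(rng, 35)
        stats = align_local(a, b)
        assert stats.score == pytest.approx(sw_score(a, b))

    def test_prefix_has_full_short_coverage(self):
        rng = np.random.default_rng(3)
        full = random_protein(rng, 100)
        stats = align_local(full, full[:70])
        assert stats.identity == 1.0
        assert stats.coverage_short == 1.0


class TestClusterAt:
    def test_identical_sequences_form_one_cluster(self, rng):
        seq = random_protein(rng, 80)
        records = make_records({"p3": seq, "p1": seq, "p2": seq})
        cs = cluster_at(records, threshold=0.9)
        assert cs.n_clusters == 1
        assert cs.clusters[0].representative == "p1"  # lexicographic tie-break
        assert sorted(cs.clusters[0].members) == ["p1", "p2", "p3"]

    def test_related_and_unrelated_split(self, rng):
        s1 = random_protein(rng, 100)
        s1p = mutate_to_identity(s1, 0.95, rng)
        s2 = random_protein(rng, 100)
        cs = cluster_at(make_records({"s1": s1, "s1p": s1p, "s2": s2}), threshold=0.9)
        groups = {frozenset(c.members) for c in cs.clusters}
        assert groups == {frozenset({"s1", "s1p"}), frozenset({"s2"})}

    def test_exact_prefix_joins_on_short_coverage(self, rng):
        full = random_protein(rng, 100)
        cs = cluster_at(make_records({"full": full, "pre": full[:70]}), threshold=0.9)
        assert cs.n_clusters == 1
        assert cs.clusters[0].representative == "full"  # longest founds first

    def test_empty_input_and_bad_threshold(self):
        with pytest.raises(InvalidInputError):
            cluster_at([], 0.9)
        with pytest.raises(InvalidParameterError):
            cluster_at(make_records({"p": PANEL}), 0.0)

    def test_members_satisfy_threshold_post_hoc(self, tiny_study):
        records = tiny_study.all_proteins()
        cs = cluster_at(records, threshold=0.9)
        assert_threshold_soundness(cs, records)


class TestCascade:
    def test_singleton_is_one_family_at_every_level(self, rng):
        records = make_records({"only": random_protein(rng, 90)})
        assignment = cascade(records)
        assert assignment.family_of == {"only": "F0000"}
        assert len(assignment.lineage["only"]) == 3

    def test_manual_cascade_fixture(self, rng):
        """90% groups the 95%-identical pair; 60% pulls in the 65% relative;
        the unrelated sequence stays alone."""
        s1 = random_protein(rng, 120)
        fixture = {
            "s1": s1,
            "s1p": mutate_to_identity(s1, 0.95, rng),
            "s1pp": mutate_to_identity(s1, 0.65, rng),
            "s2": random_protein(rng, 120),
        }
        assignment = cascade(make_records(fixture))
        fams = {}
        for pid, fam in assignment.family_of.items():
            fams.setdefault(fam, set()).add(pid)
        assert {frozenset(v) for v in fams.values()} == {
            frozenset({"s1", "s1p", "s1pp"}),
            frozenset({"s2"}),
        }
        level90 = {chain[0] for chain in (assignment.lineage[p] for p in ("s1", "s1p"))}
        assert len(level90) == 1  # the close pair merged at the first level
        assert assignment.lineage["s1pp"][0] not in level90

    def test_all_identical_collapse_to_one_family(self, rng):
        seq = random_protein(rng, 90)
        assignment = cascade(make_records({f"p{i}": seq for i in range(4)}))
        assert len(set(assignment.family_of.values())) == 1

    def test_thresholds_must_strictly_decrease(self, rng):
        records = make_records({"p": random_protein(rng, 80)})
        with pytest.raises(InvalidParameterError):
            cascade(records, thresholds=(0.9, 0.9, 0.3))

    def test_levels_coarsen_and_partition(self, tiny_study):
        records = tiny_study.all_proteins()
        assignment = cascade(records)
        assert set(assignment.family_of) == {r.protein_id for r in records}
        n_levels = [
            len({chain[i] for chain in assignment.lineage.values()}) for i in range(3)
        ]
        assert len(records) >= n_levels[0] >= n_levels[1] >= n_levels[2]

    def test_order_invariance_on_separated_fixture(self, tiny_study):
        records = tiny_study.all_proteins()
        baseline = cascade(records).family_of
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        permuted = cascade(shuffled).family_of

        def partition(mapping):
            groups = {}
            for pid, fam in mapping.items():
                groups.setdefault(fam, set()).add(pid)
            return {frozenset(g) for g in groups.values()}

        assert partition(baseline) == partition(permuted)


class TestFamilyAbundance:
    def test_counts_match_independent_tally(self, tiny_study):
        records = tiny_study.all_proteins()
        assignment = cascade(records)
        table = family_abundance(assignment, records)
        # independent tally by direct grouping
        from collections import Counter

        tally = Counter(
            (r.metagenome_id, assignment.family_of[r.protein_id]) for r in records
        )
        for (mg, fam), n in tally.items():
            assert table.loc[mg, fam] == n
        assert int(table.to_numpy().sum()) == len(records)
        per_mg = Counter(r.metagenome_id for r in records)
        for mg, n in per_mg.items():
            assert table.loc[mg].sum() == n

    def test_single_family_count(self, rng):
        seq = random_protein(rng, 80)
        records = make_records({"a": seq, "b": seq, "c": seq})
        assignment = cascade(records)
        table = family_abundance(assignment, records)
        assert table.shape == (1, 1)
        assert table.iloc[0, 0] == 3

    def test_explicit_zero_for_missing_metagenome(self, rng):
        s1, s2 = random_protein(rng, 80), random_protein(rng, 80)
        records = [
            ProteinRecord("a", "MG1", s1),
            ProteinRecord("b", "MG2", s1),
            ProteinRecord("c", "MG2", s2),
        ]
        table = family_abundance(cascade(records), records)
        fam_of_c = cascade(records).family_of["c"]
        assert table.loc["MG1", fam_of_c] == 0

    def test_unassigned_record_is_an_error(self, rng):
        records = make_records({"a": random_protein(rng, 80)})
        assignment = cascade(records)
        stranger = ProteinRecord("zzz", "MG1", random_protein(rng, 80))
        with pytest.raises(ConsistencyError):
            family_abundance(assignment, records + [stranger])


def test_length_filter_is_strict(rng):
    records = [
        ProteinRecord("short", "MG1", random_protein(rng, 50)),
        ProteinRecord("long", "MG1", random_protein(rng, 51)),
    ]
    kept = filter_by_length(records)
    assert [r.protein_id for r in kept] == ["long"]


def test_invalid_residues_rejected():
    with pytest.raises(InvalidInputError):
        ProteinRecord("bad", "MG1", "ACDB*")
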