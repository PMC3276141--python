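"""Family clustering, captured-fragment detection, distances, NJ trees."""

import io
import itertools
import random

import numpy as np
import pytest
from skbio import TreeNode

from mulescan import (
    Sequence,
    cluster_elements,
    distance_matrix,
    find_captured_fragments,
    nj_tree,
)

from conftest import random_dna


def _mutate(rng: random.Random, s: str, n: int) -> str:
    out = list(s)
    for i in rng.sample(range(len(s)), n):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestClusterElements:
    def test_identical_sequences_one_family(self, rng):
        s = random_dna(rng, 800)
        fams = cluster_elements([Sequence(f"e{i}", s) for i in range(3)])
        assert len(fams) == 1
        assert sorted(fams[0].members) == ["e0", "e1", "e2"]

    def test_unrelated_internals_separate_families(self, rng):
        seqs = [Sequence(f"e{i}", random_dna(rng, 1200)) for i in range(2)]
        assert len(cluster_elements(seqs)) == 2

    def test_threshold_splits_five_percent_divergence(self, rng):
        s = random_dna(rng, 1000)
        seqs = [Sequence("a", s), Sequence("b", _mutate(rng, s, 50))]
        assert len(cluster_elements(seqs, threshold_pct=90)) == 1
        assert len(cluster_elements(seqs, threshold_pct=97)) == 2

    def test_partition_and_order_invariance(self, rng):
        base = random_dna(rng, 900)
        seqs = [
            Sequence("a", base),
            Sequence("b", _mutate(rng, base, 20)),
            Sequence("c", random_dna(rng, 1100)),
            Sequence("d", random_dna(rng, 700)),
        ]
        ref = {
            tuple(sorted(f.members)) for f in cluster_elements(seqs)
        }
        all_ids = sorted(itertools.chain.from_iterable(ref))
        assert all_ids == ["a", "b", "c", "d"]  # a partition
        for perm in itertools.permutations(seqs):
            got = {tuple(sorted(f.members)) for f in cluster_elements(list(perm))}
            assert got == ref


class TestFindCapturedFragments:
    def test_exact_planted_fragment(self, rng):
        host = Sequence("host1", random_dna(rng, 1000))
        frag = host.residues[300:500]
        internal = Sequence(
            "int1", random_dna(rng, 400) + frag + random_dna(rng, 400)
        )
        (hit,) = find_captured_fragments(internal, [host])
        # local alignment may extend a few bp into chance-matching flank,
        # so boundaries are checked with a small slack
        assert abs(hit.element_interval[0] - 400) <= 5
        assert abs(hit.element_interval[1] - 600) <= 5
        assert abs(hit.host_interval[0] - 300) <= 5
        assert abs(hit.host_interval[1] - 500) <= 5
        assert hit.identity_pct >= 99.0
        assert hit.length >= 200

    def test_two_fragments_from_two_hosts(self, rng):
        hosts = [Sequence(f"h{i}", random_dna(rng, 800)) for i in range(2)]
        internal = Sequence(
            "int",
            random_dna(rng, 200)
            + hosts[0].residues[100:300]
            + random_dna(rng, 200)
            + hosts[1].residues[400:650]
            + random_dna(rng, 200),
        )
        frags = find_captured_fragments(internal, hosts)
        assert len(frags) == 2
        assert {f.host_seq_id for f in frags} == {"h0", "h1"}
        ivals = sorted(f.element_interval for f in frags)
        assert ivals[0][1] <= ivals[1][0]  # no overlap on the internal seq

    def test_unrelated_internal_empty(self, rng):
        host = Sequence("h", random_dna(rng, 900))
        internal = Sequence("int", random_dna(rng, 900))
        assert find_captured_fragments(internal, [host]) == []


class TestDistanceMatrix:
    def test_identical_zero_and_symmetric(self, rng):
        s = random_dna(rng, 300)
        seqs = [Sequence("a", s), Sequence("b", s), Sequence("c", random_dna(rng, 300))]
        d, labels = distance_matrix(seqs)
        assert labels == ["a", "b", "c"]
        assert d[0, 1] == 0.0
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_ten_percent_substitutions(self, rng):
        s = random_dna(rng, 500)
        seqs = [Sequence("a", s), Sequence("b", _mutate(rng, s, 50))]
        d, _ = distance_matrix(seqs)
        assert d[0, 1] == pytest.approx(0.10)


def _path_distances(newick: str) -> dict[frozenset, float]:
    tree = TreeNode.read(io.StringIO(newick))
    tips = list(tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            out[frozenset((a.name, b.name))] = a.distance(b)
    return out


class TestNjTree:
    def test_four_taxon_additive_matrix_recovered(self):
        # path metric of ((A:1,B:2):1,(C:3,D:4):1)
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        newick = nj_tree(d, labels)
        dist = _path_distances(newick)
        for i, j in itertools.combinations(range(4), 2):
            assert dist[frozenset((labels[i], labels[j]))] == pytest.approx(
                d[i, j], abs=1e-9
            )

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        newick = nj_tree(d, ["A", "B", "C"])
        dist = _path_distances(newick)
        assert dist[frozenset(("A", "B"))] == pytest.approx(4, abs=1e-9)
        assert dist[frozenset(("A", "C"))] == pytest.approx(6, abs=1e-9)
        assert dist[frozenset(("B", "C"))] == pytest.approx(8, abs=1e-9)

    def test_too_few_taxa_or_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["A", "B"])
        bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            nj_tree(bad, ["A", "B", "C"])

    def test_within_family_taxa_are_nearest_neighbors(self, rng):
        families = []
        for f in range(3):
            base = random_dna(rng, 600)
            families.append(
                [
                    Sequence(f"f{f}_a", base),
                    Sequence(f"f{f}_b", _mutate(rng, base, 12)),  # 2% apart
                ]
            )
        seqs = [s for fam in families for s in fam]
        d, labels = distance_matrix(seqs)
        newick = nj_tree(d, labels)
        dist = _path_distances(newick)
        for fam in families:
            a, b = fam[0].id, fam[1].id
            partner_d = dist[frozenset((a, b))]
            others = [
                dist[frozenset((a, other))]
                for other in labels
                if other not in (a, b)
            ]
            assert partner_d < min(others)
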