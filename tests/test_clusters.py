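"""Homogeneous/heterogeneous cluster detection against window enumeration."""

from __future__ import annotations

import random

import pytest

from cdrhmine.data_model import ClusterConfig
from cdrhmine.clusters import detect_clusters

from .conftest import make_cdrh
from .oracles import enumerate_clusters


class TestSpecifiedBehaviour:
    def test_three_nlrs_within_span_form_one_homogeneous_cluster(self):
        cdrhs = [
            make_cdrh("g1", start=1, length=1000, rga_class="TNL"),
            make_cdrh("g2", start=80_001, length=1000, rga_class="TNL"),
            make_cdrh("g3", start=150_001, length=1000, rga_class="TNL"),
        ]
        (cl,) = detect_clusters(cdrhs)
        assert cl.kind == "HOMOG_NLR"
        assert cl.member_ids == ["g1", "g2", "g3"]
        assert cl.span_bp <= 200_000

    def test_nl_plus_rlk_pair_is_heterogeneous(self):
        cdrhs = [
            make_cdrh("g1", start=1, rga_class="NL"),
            make_cdrh("g2", start=50_001, rga_class="LRR_RLK"),
        ]
        (cl,) = detect_clusters(cdrhs)
        assert cl.kind == "HETEROGENEOUS"

    def test_rlp_with_non_rga_neighbour_is_heterogeneous(self):
        cdrhs = [
            make_cdrh("g1", start=1, rga_class="LRR_RLP"),
            make_cdrh("g2", start=10_001, rga_class="NON_RGA"),
        ]
        (cl,) = detect_clusters(cdrhs)
        assert cl.kind == "HETEROGENEOUS"

    def test_member_cap_closes_cluster_at_eight(self):
        cdrhs = [
            make_cdrh(f"g{i}", start=1 + i * 10_000, length=1000, rga_class="TNL")
            for i in range(9)
        ]
        clusters = detect_clusters(cdrhs)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 8
        assert "g8" not in clusters[0].member_ids

    def test_two_nlrs_beyond_span_do_not_cluster(self):
        cdrhs = [
            make_cdrh("g1", start=1, length=100, rga_class="TNL"),
            make_cdrh("g2", start=250_001, length=100, rga_class="TNL"),
        ]
        assert detect_clusters(cdrhs) == []

    def test_non_rga_only_windows_are_discarded(self):
        cdrhs = [
            make_cdrh("g1", start=1, rga_class="NON_RGA"),
            make_cdrh("g2", start=10_001, rga_class="NON_RGA"),
        ]
        assert detect_clusters(cdrhs) == []

    def test_homogeneous_pass_takes_precedence(self):
        # two TNLs consume each other; the lone non-RGA has no partner left
        cdrhs = [
            make_cdrh("g1", start=1, rga_class="TNL"),
            make_cdrh("g2", start=10_001, rga_class="TNL"),
            make_cdrh("g3", start=20_001, rga_class="NON_RGA"),
        ]
        clusters = detect_clusters(cdrhs)
        assert [cl.kind for cl in clusters] == ["HOMOG_NLR"]

    def test_chromosomes_are_independent(self):
        cdrhs = [
            make_cdrh("g1", chrom="A01", start=1, rga_class="TNL"),
            make_cdrh("g2", chrom="C01", start=10_001, rga_class="TNL"),
        ]
        assert detect_clusters(cdrhs) == []


SUPERCLASS_POOL = ["TNL", "CNL", "NL", "LRR_RLK", "OTHER_RLK", "LRR_RLP", "NON_RGA"]


def _random_instance(rng, n):
    cdrhs = []
    for i in range(n):
        start = rng.randrange(1, 600_000)
        cdrhs.append(
            make_cdrh(
                f"g{i}",
                start=start,
                length=rng.randrange(500, 5000),
                rga_class=rng.choice(SUPERCLASS_POOL),
            )
        )
    return cdrhs


class TestOracleEquivalence:
    def test_matches_window_enumeration_on_random_instances(self):
        """Greedy detection equals the independent left-to-right
        maximal-window enumeration on random single-chromosome instances."""
        rng = random.Random(2024)
        cfg = ClusterConfig()
        for trial in range(150):
            cdrhs = _random_instance(rng, rng.randint(0, 15))
            got = detect_clusters(cdrhs, cfg)

            ordered = sorted(cdrhs, key=lambda c: (c.gene.start, c.gene.gene_id))
            expected = []
            consumed = set()
            for superclass, kind in (("NLR", "HOMOG_NLR"), ("RLK", "HOMOG_RLK"),
                                     ("RLP", "HOMOG_RLP")):
                pool = [c for c in ordered if c.superclass == superclass]
                ivs = [(c.gene.start, c.gene.end) for c in pool]
                for win in enumerate_clusters(ivs, cfg.span_bp, 2, cfg.max_members_homog):
                    members = [pool[k] for k in win]
                    expected.append((kind, tuple(m.gene.gene_id for m in members)))
                    consumed.update(id(m) for m in members)
            remaining = [c for c in ordered if id(c) not in consumed]
            ivs = [(c.gene.start, c.gene.end) for c in remaining]
            for win in enumerate_clusters(ivs, cfg.span_bp, 2, None):
                members = [remaining[k] for k in win]
                classes = {m.superclass for m in members}
                rga = classes - {"NON_RGA"}
                if len(rga) >= 2 or (rga and "NON_RGA" in classes):
                    expected.append(
                        ("HETEROGENEOUS", tuple(m.gene.gene_id for m in members))
                    )

            got_set = {(cl.kind, tuple(cl.member_ids)) for cl in got}
            assert got_set == set(expected), f"trial {trial}"

    def test_output_independent_of_input_order(self):
        rng = random.Random(7)
        cdrhs = _random_instance(rng, 12)
        base = detect_clusters(cdrhs)
        for _ in range(5):
            shuffled = cdrhs[:]
            rng.shuffle(shuffled)
            again = detect_clusters(shuffled)
            assert [(c.kind, c.member_ids) for c in again] == [
                (c.kind, c.member_ids) for c in base
            ]

    def test_every_emitted_cluster_respects_invariants(self):
        rng = random.Random(11)
        cfg = ClusterConfig()
        for _ in range(50):
            for cl in detect_clusters(_random_instance(rng, 15), cfg):
                assert cl.span_bp <= cfg.span_bp
                assert len(cl.members) >= cfg.min_members
                if cl.kind.startswith("HOMOG"):
                    assert len(cl.members) <= cfg.max_members_homog
                    assert len(cl.superclasses) == 1
                else:
                    rga = cl.superclasses - {"NON_RGA"}
                    assert len(rga) >= 2 or (rga and "NON_RGA" in cl.superclasses)
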