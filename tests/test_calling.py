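"""Window-rule cluster calling, censuses, the PepM motif screen and
fatty-acid-synthase conflict resolution."""

import re

import numpy as np
import pytest

from bgcfam.calling import (
    call_clusters,
    census,
    nrps_pks_ratio,
    resolve_fas_conflicts,
    scan_pepm_motif,
)
from bgcfam.model import AMINO_ACIDS, ClassCensus

from conftest import make_genome, make_hit


def oracle_intervals(indices, n, w):
    """Independent oracle: build +/-w intervals around each hit index and
    iteratively merge overlapping ones."""
    ivs = sorted((max(0, i - w), min(n - 1, i + w)) for i in indices)
    merged = []
    for first, last in ivs:
        if merged and first <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], last)
        else:
            merged.append([first, last])
    return [tuple(m) for m in merged]


class TestCallClusters:
    def test_single_hit_extends_six_genes_each_side(self):
        genome = make_genome("G", 100)
        (c,) = call_clusters([make_hit(genome, 10)], genome)
        assert (c.first_index, c.last_index) == (4, 16)
        assert c.n_genes == 13
        assert c.cluster_id == "G_1"

    def test_window_clips_at_replicon_start(self):
        genome = make_genome("G", 20)
        (c,) = call_clusters([make_hit(genome, 3)], genome)
        assert (c.first_index, c.last_index) == (0, 9)

    def test_hits_within_window_join_one_cluster(self):
        genome = make_genome("G", 100)
        hits = [make_hit(genome, 10), make_hit(genome, 15, "PKS1")]
        (c,) = call_clusters(hits, genome)
        assert (c.first_index, c.last_index) == (4, 21)
        assert c.class_set == {"NRPS", "PKS1"}

    def test_overlapping_extensions_merge_into_one_locus(self):
        genome = make_genome("G", 100)
        hits = [make_hit(genome, 10), make_hit(genome, 20)]
        # gap 10 > w: separate chains, but the +/-6 extensions overlap
        (c,) = call_clusters(hits, genome)
        assert (c.first_index, c.last_index) == (4, 26)
        assert len(c.hits) == 2
        # merging off exposes the two overlapping chains
        two = call_clusters(hits, genome, merge_overlapping_extensions=False)
        assert [(c.first_index, c.last_index) for c in two] == [(4, 16), (14, 26)]
        # the looser join reading chains them directly
        (c2,) = call_clusters(
            hits, genome, join_rule="extensions_overlap",
            merge_overlapping_extensions=False,
        )
        assert (c2.first_index, c2.last_index) == (4, 26)

    def test_distant_hits_stay_separate(self):
        genome = make_genome("G", 100)
        hits = [make_hit(genome, 10), make_hit(genome, 40)]
        cs = call_clusters(hits, genome)
        assert [(c.first_index, c.last_index) for c in cs] == [(4, 16), (34, 46)]
        assert [c.cluster_id for c in cs] == ["G_1", "G_2"]

    def test_non_significant_hit_rejected(self):
        genome = make_genome("G", 50)
        with pytest.raises(ValueError, match="non-significant"):
            call_clusters([make_hit(genome, 5, significant=False)], genome)

    def test_unknown_replicon_rejected(self):
        genome = make_genome("G", 50)
        h = make_hit(genome, 5)
        h.replicon_id = "nope"
        with pytest.raises(KeyError, match="nope"):
            call_clusters([h], genome)

    @pytest.mark.parametrize("join_rule", ["hit_in_window", "extensions_overlap"])
    def test_matches_interval_merge_oracle(self, join_rule):
        rng = np.random.default_rng(3)
        genome_cache = {}
        for _ in range(200):
            n = int(rng.integers(20, 201))
            genome = genome_cache.setdefault(n, make_genome("G", n))
            k = int(rng.integers(1, 21))
            indices = sorted(set(rng.integers(0, n, size=k).tolist()))
            w = int(rng.integers(0, 9))
            hits = [make_hit(genome, i) for i in indices]
            clusters = call_clusters(hits, genome, w=w, join_rule=join_rule)
            got = [(c.first_index, c.last_index) for c in clusters]
            assert got == oracle_intervals(indices, n, w)
            # every hit in exactly one cluster; ranges disjoint
            assert sum(len(c.hits) for c in clusters) == len(hits)
            for a, b in zip(clusters, clusters[1:]):
                assert a.last_index < b.first_index

    def test_growing_window_is_monotone(self):
        rng = np.random.default_rng(5)
        genome = make_genome("G", 150)
        indices = sorted(set(rng.integers(0, 150, size=8).tolist()))
        hits = [make_hit(genome, i) for i in indices]
        prev = None
        for w in range(0, 12):
            clusters = call_clusters(hits, genome, w=w)
            spans = [(c.first_index, c.last_index) for c in clusters]
            if prev is not None:
                assert len(clusters) <= len(prev)
                total_prev = sum(b - a + 1 for a, b in prev)
                total_now = sum(b - a + 1 for a, b in spans)
                assert total_now >= total_prev
            prev = spans


class TestCensus:
    def test_hybrid_counts_once_per_class(self):
        genome = make_genome("G", 50)
        hits = [make_hit(genome, 10, "NRPS"), make_hit(genome, 12, "PKS1")]
        (c,) = call_clusters(hits, genome)
        result = census([c])
        assert result.class_counts == {"NRPS": 1, "PKS1": 1}
        assert result.n_clusters == 1

    def test_empty_census(self):
        result = census([], genome_id="G")
        assert result.class_counts == {} and result.n_clusters == 0

    def test_random_clusters_match_direct_recount(self):
        rng = np.random.default_rng(9)
        genome = make_genome("G", 500)
        classes = ["NRPS", "PKS1", "PKS2", "terpene", "lanthipeptide"]
        positions = rng.choice(np.arange(5, 495, 20), size=10, replace=False)
        clusters = []
        expect: dict[str, int] = {}
        for p in sorted(positions.tolist()):
            cls = [classes[i] for i in rng.choice(5, size=rng.integers(1, 3), replace=False)]
            hits = [make_hit(genome, p + k, c) for k, c in enumerate(cls)]
            clusters.extend(call_clusters(hits, genome, w=2))
            for c in set(cls):
                expect[c] = expect.get(c, 0) + 1
        result = census(clusters)
        assert result.class_counts == expect
        assert result.n_clusters == 10


class TestRatio:
    def test_ratio_arithmetic(self):
        c1 = ClassCensus("a", {"NRPS": 14, "PKS1": 3, "PKS2": 2}, 19)
        assert nrps_pks_ratio([c1]) == pytest.approx(2.8)
        c2 = ClassCensus("b", {"NRPS": 9, "PKS1": 10, "PKS2": 6, "PKS3": 4}, 29)
        assert nrps_pks_ratio([c2]) == pytest.approx(0.45)
        assert nrps_pks_ratio([ClassCensus("c", {"PKS1": 7}, 7)]) == 0.0

    def test_zero_pks_denominator_is_undefined(self):
        assert nrps_pks_ratio([ClassCensus("a", {"NRPS": 5}, 5)]) is None


class TestPepMScreen:
    def test_motif_hit_records_position(self):
        hits = scan_pepm_motif({"p1": "MEDKAAAAANSW"})
        assert len(hits) == 1
        assert hits[0].sm_class == "phosphonate"
        assert hits[0].motif_position == 2

    def test_four_residue_spacer_is_no_hit(self):
        assert scan_pepm_motif({"p1": "MEDKAAAANSW"}) == []

    def test_agrees_with_regex_oracle_on_planted_sequences(self):
        rng = np.random.default_rng(17)
        pattern = re.compile("EDK.{5}NS")
        seqs = {}
        for i in range(200):
            length = int(rng.integers(20, 200))
            s = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=length))
            if i % 3 == 0:  # plant a motif at a random feasible position
                pos = int(rng.integers(0, length - 10))
                s = s[:pos] + "EDK" + s[pos + 3 : pos + 8] + "NS" + s[pos + 10 :]
            seqs[f"p{i}"] = s
        got = {h.locus_tag: h.motif_position for h in scan_pepm_motif(seqs)}
        for locus, s in seqs.items():
            m = pattern.search(s)
            if m:
                assert got[locus] == m.start() + 1
            else:
                assert locus not in got

    def test_odd_characters_warn_but_scan(self):
        with pytest.warns(UserWarning, match="alphabet"):
            hits = scan_pepm_motif({"p1": "MEDKAB+DENSW"})
        assert hits and hits[0].motif_position == 2


class TestFasConflicts:
    def test_fas_dominated_pks_hit_removed(self):
        genome = make_genome("G", 50)
        h = make_hit(genome, 10, "PKS1", score=80.0)
        assert resolve_fas_conflicts([h], {h.locus_tag: 120.0}) == []

    def test_pks_hit_beating_fas_retained(self):
        genome = make_genome("G", 50)
        h = make_hit(genome, 10, "PKS1", score=120.0)
        assert resolve_fas_conflicts([h], {h.locus_tag: 80.0}) == [h]

    def test_no_table_is_pass_through_and_non_pks_untouched(self):
        genome = make_genome("G", 50)
        pks = make_hit(genome, 10, "PKS1", score=80.0)
        nrps = make_hit(genome, 20, "NRPS", score=80.0)
        assert resolve_fas_conflicts([pks, nrps], None) == [pks, nrps]
        assert resolve_fas_conflicts([nrps], {nrps.locus_tag: 500.0}) == [nrps]
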