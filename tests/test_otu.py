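"""Open-reference clustering, taxonomy transfer, bimera screen, OTU table."""

import numpy as np
import pandas as pd
import pytest

from culturoscope.otu import (BimeraParams, Otu, build_otu_table,
                              assign_taxonomy, flag_bimeras,
                              pick_otus_open_reference)
from culturoscope.seq import SequenceRecord, percent_identity
from culturoscope.simulate import ReferenceDb, generate_reference_db, mutate_to_divergence
from conftest import random_dna


def naive_greedy_oracle(reads, refdb, threshold=97.0):
    """Independent re-enumeration of the open-reference greedy rule.

    Returns a frozenset of frozensets of read ids (the partition).
    """
    groups = {}
    for r in reads:
        groups.setdefault(r.bases, []).append(r.id)
    closed, leftovers = {}, []
    for seq, ids in groups.items():
        hits = sorted(
            ((percent_identity(seq, refdb.v1v2(rid)), rid) for rid in refdb.ids),
            key=lambda t: (-t[0], t[1]))
        if hits and hits[0][0] >= threshold:
            closed.setdefault(hits[0][1], []).extend(ids)
        else:
            leftovers.append(seq)
    leftovers.sort(key=lambda s: (-len(groups[s]), -len(s), min(groups[s])))
    centroids, members = [], []
    for seq in leftovers:
        for ci, cen in enumerate(centroids):
            if percent_identity(seq, cen) >= threshold:
                members[ci].extend(groups[seq])
                break
        else:
            centroids.append(seq)
            members.append(list(groups[seq]))
    parts = [frozenset(ids) for ids in closed.values()] + \
            [frozenset(ids) for ids in members]
    return frozenset(parts)


def mini_refdb(seqs: dict[str, str]) -> ReferenceDb:
    records = [SequenceRecord(k, v) for k, v in seqs.items()]
    tax = {k: f"p__P; c__C; o__O; f__F; g__G{k}; s__S{k}" for k in seqs}
    return ReferenceDb(records, tax, (0, len(next(iter(seqs.values())))))


class TestPickOtus:
    def test_reads_identical_to_reference(self):
        rng = np.random.default_rng(1)
        ref = random_dna(rng, 250)
        db = mini_refdb({"R1": ref})
        reads = [SequenceRecord(f"r{i}", ref) for i in range(3)]
        otus = pick_otus_open_reference(reads, db)
        assert len(otus) == 1 and otus[0].otu_id == "R1" and otus[0].origin == "closed"
        assert sorted(otus[0].members) == ["r0", "r1", "r2"]

    def test_dissimilar_reads_found_two_denovo_otus(self):
        rng = np.random.default_rng(2)
        db = mini_refdb({"R1": random_dna(rng, 250)})
        a = random_dna(rng, 250)
        b = mutate_to_divergence(SequenceRecord("a", a), 10, seed=1).bases
        otus = pick_otus_open_reference(
            [SequenceRecord("r1", a), SequenceRecord("r2", b)], db)
        denovo = [o for o in otus if o.origin == "denovo"]
        assert len(denovo) == 2

    def test_empty_read_set(self, refdb_small):
        assert pick_otus_open_reference([], refdb_small) == []

    def test_members_within_threshold_of_centroid(self, refdb_small):
        rng = np.random.default_rng(3)
        base = random_dna(rng, 300)
        reads = [SequenceRecord(f"r{i}",
                                mutate_to_divergence(SequenceRecord("b", base),
                                                     1.0, seed=i).bases)
                 for i in range(6)]
        otus = pick_otus_open_reference(reads, refdb_small)
        for o in otus:
            if o.origin == "denovo":
                for rid in o.members:
                    read = next(r for r in reads if r.id == rid)
                    assert percent_identity(read.bases, o.representative.bases) >= 97

    def test_permutation_invariance(self, refdb_small):
        rng = np.random.default_rng(4)
        base = random_dna(rng, 200)
        reads = [SequenceRecord(f"r{i}", base if i % 2 else
                                mutate_to_divergence(SequenceRecord("b", base),
                                                     6.0, seed=9).bases)
                 for i in range(6)]
        p1 = pick_otus_open_reference(reads, refdb_small)
        p2 = pick_otus_open_reference(list(reversed(reads)), refdb_small)
        assert {frozenset(o.members) for o in p1} == {frozenset(o.members) for o in p2}

    def test_matches_naive_oracle_on_random_instances(self, refdb_small):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n_reads = int(rng.integers(2, 12))
            bases = []
            for _r in range(n_reads):
                if rng.random() < 0.5 and bases:
                    parent = bases[int(rng.integers(len(bases)))]
                    bases.append(mutate_to_divergence(
                        SequenceRecord("p", parent), float(rng.uniform(0, 8)),
                        seed=int(rng.integers(2**31)), tolerance=2.0).bases)
                elif rng.random() < 0.5:
                    rid = refdb_small.ids[int(rng.integers(len(refdb_small.ids)))]
                    win = refdb_small.v1v2(rid)[:120]
                    bases.append(mutate_to_divergence(
                        SequenceRecord("p", win), float(rng.uniform(0, 5)),
                        seed=int(rng.integers(2**31)), tolerance=2.0).bases)
                else:
                    bases.append(random_dna(rng, int(rng.integers(60, 130))))
            reads = [SequenceRecord(f"r{i:02d}", b) for i, b in enumerate(bases)]
            got = {frozenset(o.members)
                   for o in pick_otus_open_reference(reads, refdb_small)}
            assert got == set(naive_greedy_oracle(reads, refdb_small))


class TestAssignTaxonomy:
    def test_closed_inherits_full_lineage(self, refdb_small):
        rid = refdb_small.ids[0]
        otu = Otu(rid, SequenceRecord(rid, refdb_small.v1v2(rid)), ["r1"],
                  origin="closed")
        assert assign_taxonomy(otu, refdb_small) == refdb_small.taxonomy[rid]

    @pytest.mark.parametrize("divergence,n_ranks", [
        (4.0, 5),    # ~96% -> genus level
        (6.0, 4),    # ~94% -> family level
        (12.0, 3),   # ~88% -> order level
        (17.0, 2),   # ~83% -> class/phylum level
    ])
    def test_band_truncation(self, refdb_small, divergence, n_ranks):
        rid = refdb_small.ids[0]
        rep = mutate_to_divergence(SequenceRecord(rid, refdb_small.v1v2(rid)),
                                   divergence, seed=13)
        otu = Otu("denovo1", rep, ["r1"], origin="denovo")
        lineage = assign_taxonomy(otu, refdb_small)
        assert len(lineage.split("; ")) == n_ranks
        assert refdb_small.taxonomy[rid].startswith(lineage)

    def test_floor_is_unassigned(self, refdb_small):
        rep = SequenceRecord("denovo1", random_dna(np.random.default_rng(7), 300))
        otu = Otu("denovo1", rep, ["r1"], origin="denovo")
        assert assign_taxonomy(otu, refdb_small) == "Unassigned"


class TestFlagBimeras:
    def _db(self):
        rng = np.random.default_rng(8)
        return mini_refdb({"A": random_dna(rng, 240), "B": random_dna(rng, 240)})

    def test_reference_copy_not_flagged(self):
        db = self._db()
        otu = Otu("denovo1", SequenceRecord("denovo1", db.v1v2("A")), ["r1"])
        flag_bimeras([otu], db)
        assert not otu.chimera_flag

    def test_perfect_crossover_flagged(self):
        db = self._db()
        chimera = db.v1v2("A")[:120] + db.v1v2("B")[120:]
        otu = Otu("denovo1", SequenceRecord("denovo1", chimera), ["r1"])
        flag_bimeras([otu], db)
        assert otu.chimera_flag

    def test_flags_invariant_to_parent_order(self):
        db = self._db()
        rev = mini_refdb({"B": db.v1v2("B"), "A": db.v1v2("A")})
        chimera = db.v1v2("A")[:120] + db.v1v2("B")[120:]
        o1 = Otu("denovo1", SequenceRecord("denovo1", chimera), ["r1"])
        o2 = Otu("denovo1", SequenceRecord("denovo1", chimera), ["r1"])
        flag_bimeras([o1], db)
        flag_bimeras([o2], rev)
        assert o1.chimera_flag == o2.chimera_flag


class TestOtuTable:
    def _otus(self):
        rng = np.random.default_rng(9)
        return [
            Otu("O1", SequenceRecord("O1", random_dna(rng, 200)),
                ["r1", "r2", "r3"]),
            Otu("O2", SequenceRecord("O2", random_dna(rng, 200)), ["r4"],
                chimera_flag=True),
        ]

    def test_counts_tallied(self):
        table = build_otu_table(self._otus()[:1],
                                {"r1": "S1", "r2": "S1", "r3": "S1"},
                                drop_flagged=False)
        assert table.counts.loc["S1", "O1"] == 3

    def test_flagged_otu_dropped(self):
        mapping = {"r1": "S1", "r2": "S1", "r3": "S1", "r4": "S1"}
        with_flagged = build_otu_table(self._otus(), mapping, drop_flagged=False)
        dropped = build_otu_table(self._otus(), mapping, drop_flagged=True)
        assert "O2" in with_flagged.counts.columns
        assert "O2" not in dropped.counts.columns
        assert dropped.counts.loc["S1"].sum() == with_flagged.counts.loc["S1"].sum() - 1

    def test_unmapped_read_is_error(self):
        with pytest.raises(KeyError):
            build_otu_table(self._otus()[:1], {"r1": "S1"}, drop_flagged=False)

    def test_row_sums_conserved(self, noise_free_run):
        """OTU-table row sums equal per-sample retained read counts."""
        retained = noise_free_run.report.retained_counts()
        sums = noise_free_run.table.counts.sum(axis=1)
        for sample, n in retained.items():
            assert sums.get(sample, 0) == n
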