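"""Synthetic-data generator: determinism, divergence targets, plating."""

import numpy as np
import pytest

from culturoscope.demux import FilterParams, ManifestEntry, SampleManifest, filter_library
from culturoscope.seq import SequenceRecord, percent_identity
from culturoscope.simulate import (CommunityProfile, ErrorModel, NOISE_FREE,
                                   NovelSpec, PlatingScenario, demo_scenario,
                                   generate_barcodes, generate_reference_db,
                                   mutate_to_divergence, run_simulation,
                                   simulate_colony_pick, simulate_community,
                                   simulate_plating, simulate_reads,
                                   FWD_PRIMER, REV_PRIMER)


class TestReferenceDb:
    def test_seeded_determinism(self):
        a = generate_reference_db(3, seed=1)
        b = generate_reference_db(3, seed=1)
        assert [r.bases for r in a.records] == [r.bases for r in b.records]

    def test_pairwise_window_dissimilarity(self, refdb_small):
        ids = refdb_small.ids
        for i, x in enumerate(ids):
            for y in ids[i + 1:]:
                assert percent_identity(refdb_small.v1v2(x), refdb_small.v1v2(y)) < 90

    def test_single_entry_db(self):
        db = generate_reference_db(1, seed=2)
        assert len(db) == 1 and db.ids[0] in db.taxonomy

    def test_io_roundtrip(self, refdb_small, tmp_path):
        refdb_small.write(tmp_path / "r.fasta", tmp_path / "t.tsv")
        back = type(refdb_small).read(tmp_path / "r.fasta", tmp_path / "t.tsv")
        assert back.ids == refdb_small.ids
        assert back.v1v2_span == refdb_small.v1v2_span
        assert back.taxonomy == refdb_small.taxonomy


class TestMutateToDivergence:
    def test_zero_target_identical(self, refdb_small):
        parent = SequenceRecord("p", refdb_small.v1v2(refdb_small.ids[0]))
        assert mutate_to_divergence(parent, 0, seed=1).bases == parent.bases

    @pytest.mark.parametrize("target", [5.0, 11.0, 18.0])
    def test_target_hit_within_half_point(self, refdb_small, target):
        parent = SequenceRecord("p", refdb_small.v1v2(refdb_small.ids[0]))
        child = mutate_to_divergence(parent, target, seed=9)
        assert percent_identity(parent, child) == pytest.approx(100 - target, abs=0.5)

    def test_out_of_range_rejected(self, refdb_small):
        parent = SequenceRecord("p", refdb_small.v1v2(refdb_small.ids[0]))
        with pytest.raises(ValueError):
            mutate_to_divergence(parent, 30, seed=1)


class TestSimulateCommunity:
    def test_single_taxon(self, refdb_small):
        prof = simulate_community(refdb_small, 1, seed=4)
        assert list(prof.abundances.values()) == [1.0]

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_abundances_sum_to_one(self, refdb_small, seed):
        prof = simulate_community(refdb_small, 5, seed=seed)
        assert sum(prof.abundances.values()) == pytest.approx(1.0, abs=1e-9)

    def test_novel_member_is_novel_under_rule(self, refdb_small):
        prof = simulate_community(refdb_small, 3, novel_spec=[NovelSpec(8.0)], seed=6)
        (nid,) = prof.novel_members
        best = max(percent_identity(prof.templates[nid], refdb_small.v1v2(r))
                   for r in refdb_small.ids)
        assert best <= 95.0  # planted 8% divergence implies novelty


def _two_taxon_profile():
    return CommunityProfile({"A": 0.7, "B": 0.3},
                            {"A": "ACGT" * 60, "B": "TTGCA" * 48})


class TestSimulatePlating:
    def test_single_grower_no_carryover(self):
        prof = _two_taxon_profile()
        scraped, truth = simulate_plating(
            prof, PlatingScenario(growth_prob={"A": 1.0}, carryover_reads_fraction=0.0))
        assert scraped.abundances == {"A": 1.0}
        assert truth.grown == {"A"}

    def test_full_carryover_equals_inoculum(self):
        prof = _two_taxon_profile()
        scraped, _ = simulate_plating(
            prof, PlatingScenario(growth_prob={}, carryover_reads_fraction=1.0))
        assert scraped.abundances == pytest.approx(prof.abundances)

    def test_dominance_raises_relative_abundance(self):
        prof = _two_taxon_profile()
        plain, _ = simulate_plating(
            prof, PlatingScenario(growth_prob={"A": 1.0, "B": 1.0},
                                  carryover_reads_fraction=0.1))
        boosted, _ = simulate_plating(
            prof, PlatingScenario(growth_prob={"A": 1.0, "B": 1.0},
                                  dominance_factor=50.0, dominant_taxon="B",
                                  carryover_reads_fraction=0.1))
        assert boosted.abundances["B"] > plain.abundances["B"]
        assert boosted.abundances["B"] > prof.abundances["B"]

    def test_non_grower_recorded_not_grown(self):
        prof = _two_taxon_profile()
        scraped, truth = simulate_plating(
            prof, PlatingScenario(growth_prob={"A": 1.0}, carryover_reads_fraction=0.05))
        assert "B" in scraped.abundances and "B" not in truth.grown


class TestColonyPick:
    def test_zero_colonies(self):
        picks = simulate_colony_pick(_two_taxon_profile(),
                                     PlatingScenario(growth_prob={"A": 1.0}), 0)
        assert picks == []

    def test_single_taxon_profile(self):
        picks = simulate_colony_pick(
            CommunityProfile({"A": 1.0}, {"A": "ACGT" * 60}),
            PlatingScenario(growth_prob={"A": 1.0}, pick_cap_per_taxon=10), 5, seed=3)
        assert len(picks) == 5 and all(t == "A" for _c, t in picks)

    def test_per_taxon_cap_enforced(self):
        """At most three colonies of one morphology are picked per plate."""
        picks = simulate_colony_pick(
            CommunityProfile({"A": 1.0}, {"A": "ACGT" * 60}),
            PlatingScenario(growth_prob={"A": 1.0}, pick_cap_per_taxon=3), 10, seed=3)
        assert len(picks) == 3


def _mini_manifest():
    rng = np.random.default_rng(5)
    bcs = generate_barcodes(3, rng)
    return SampleManifest([
        ManifestEntry("S1", bcs[0], FWD_PRIMER, REV_PRIMER, role="inoculum"),
        ManifestEntry("S2", bcs[1], FWD_PRIMER, REV_PRIMER, role="scraped",
                      colonies=30),
    ])


class TestSimulateReads:
    def test_noise_free_reads_demultiplex_exactly(self):
        manifest = _mini_manifest()
        profiles = {"S1": _two_taxon_profile(), "S2": _two_taxon_profile()}
        reads, truth = simulate_reads(profiles, manifest, NOISE_FREE, 25, seed=8)
        clean, report = filter_library(reads, manifest,
                                       FilterParams(min_length=100))
        assert report.n_retained == len(reads)
        for target, rds in clean.items():
            for r in rds:
                assert truth.read_sample[r.id] == target
                assert r.bases == truth.templates[truth.read_taxon[r.id]]

    def test_heavy_primer_errors_fail_primer_filter(self):
        manifest = _mini_manifest()
        profiles = {"S1": _two_taxon_profile()}
        noisy = ErrorModel(substitution_rate=0.5, homopolymer_indel_rate=0.0,
                           bad_segment_prob=0.0)
        reads, _ = simulate_reads(profiles, manifest, noisy, 30, seed=8)
        _clean, report = filter_library(reads, manifest, FilterParams(min_length=100))
        assert report.n_retained == 0

    def test_homopolymer_indels_lengthen_runs(self):
        rng = np.random.default_rng(1)
        model = ErrorModel(substitution_rate=0.0, homopolymer_indel_rate=0.2,
                           bad_segment_prob=0.0)
        template = "ACGT" * 10 + "AAAAAA" + "CGTA" * 10
        grew = 0
        n = 200
        for _ in range(n):
            out, _s, _i = model.corrupt(template, rng)
            if "AAAAAAA" in out:
                grew += 1
        # the 6-base run gains a base with p ~ rate*6/2 = 0.6 capped at 0.5,
        # then halved for the grow-vs-shrink coin: expect roughly 25%
        assert 0.10 < grew / n < 0.45

    def test_byte_reproducibility(self):
        manifest = _mini_manifest()
        profiles = {"S1": _two_taxon_profile()}
        r1, _ = simulate_reads(profiles, manifest, ErrorModel(), 20, seed=9)
        r2, _ = simulate_reads(profiles, manifest, ErrorModel(), 20, seed=9)
        assert [(r.id, r.bases, r.quality) for r in r1] == \
               [(r.id, r.bases, r.quality) for r in r2]


class TestScenario:
    def test_run_simulation_reproducible(self, tmp_path):
        sc = demo_scenario(n_reference_types=6, n_taxa_per_sponge=4,
                           reads_per_sample=10, reads_per_colony=4)
        a = run_simulation(sc, 21, outdir=tmp_path / "a")
        b = run_simulation(sc, 21, outdir=tmp_path / "b")
        assert (tmp_path / "a" / "reads.fastq").read_bytes() == \
               (tmp_path / "b" / "reads.fastq").read_bytes()
        assert (tmp_path / "a" / "manifest.tsv").read_bytes() == \
               (tmp_path / "b" / "manifest.tsv").read_bytes()

    def test_ground_truth_consistent_with_reads(self, tmp_path):
        sc = demo_scenario(n_reference_types=6, n_taxa_per_sponge=4,
                           reads_per_sample=12, reads_per_colony=4,
                           error_model=NOISE_FREE)
        res = run_simulation(sc, 5)
        by_sample: dict[str, int] = {}
        for rid, sid in res.truth.read_sample.items():
            by_sample[sid] = by_sample.get(sid, 0) + 1
        for e in res.manifest:
            expected = 4 if e.role == "colony" else 12
            assert by_sample.get(e.sample_id, 0) == expected
        # read-level taxon provenance matches the declared compositions
        for rid, taxon in res.truth.read_taxon.items():
            sid = res.truth.read_sample[rid]
            assert res.truth.sample_composition[sid].get(taxon, 0) > 0
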