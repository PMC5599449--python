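"""Demultiplexing partitions and the four quality-filter rules."""

import numpy as np
import pytest

from culturoscope.demux import (DEFAULT_ADAPTOR, FilterParams, ManifestEntry,
                                SampleManifest, demultiplex_forward,
                                demultiplex_reverse, filter_library,
                                longest_homopolymer, quality_filter)
from culturoscope.seq import SequenceRecord, reverse_complement
from culturoscope.simulate import (FWD_PRIMER, REV_PRIMER, NOISE_FREE,
                                   CommunityProfile, generate_barcodes,
                                   simulate_reads)
from conftest import random_dna


@pytest.fixture(scope="module")
def barcodes():
    return generate_barcodes(6, np.random.default_rng(3))


@pytest.fixture(scope="module")
def manifest(barcodes):
    return SampleManifest([
        ManifestEntry("S1", barcodes[0], FWD_PRIMER, REV_PRIMER, role="scraped",
                      colonies=25, sponge="AA"),
        ManifestEntry("S2", barcodes[1], FWD_PRIMER, REV_PRIMER, role="inoculum",
                      sponge="AA"),
        ManifestEntry("C1", barcodes[2], FWD_PRIMER, REV_PRIMER,
                      rev_barcode=barcodes[4], role="colony", plate_group="P1"),
        ManifestEntry("C2", barcodes[2], FWD_PRIMER, REV_PRIMER,
                      rev_barcode=barcodes[5], role="colony", plate_group="P1"),
    ])


def make_read(rid, barcode, template, primer=None, rev_barcode=None, qual=38):
    primer = primer if primer is not None else FWD_PRIMER.replace("Y", "T").replace("M", "A")
    bases = DEFAULT_ADAPTOR + barcode + primer + template + reverse_complement(REV_PRIMER)
    if rev_barcode:
        bases += reverse_complement(rev_barcode)
    return SequenceRecord(rid, bases, [qual] * len(bases))


@pytest.fixture(scope="module")
def template():
    return random_dna(np.random.default_rng(8), 260)


class TestManifest:
    def test_barcode_collision_rejected(self, barcodes):
        with pytest.raises(ValueError):
            SampleManifest([
                ManifestEntry("A", barcodes[0], FWD_PRIMER, REV_PRIMER),
                ManifestEntry("B", barcodes[0], FWD_PRIMER, REV_PRIMER),
            ])

    def test_duplicate_pair_rejected(self, barcodes):
        with pytest.raises(ValueError):
            SampleManifest([
                ManifestEntry("C1", barcodes[0], FWD_PRIMER, REV_PRIMER,
                              rev_barcode=barcodes[1], role="colony", plate_group="P"),
                ManifestEntry("C2", barcodes[0], FWD_PRIMER, REV_PRIMER,
                              rev_barcode=barcodes[1], role="colony", plate_group="P"),
            ])

    def test_tsv_roundtrip(self, manifest, tmp_path):
        p = tmp_path / "m.tsv"
        manifest.to_tsv(p)
        back = SampleManifest.from_tsv(p)
        assert [vars(e) for e in back] == [vars(e) for e in manifest]


class TestDemultiplexForward:
    def test_exact_match_assigns(self, manifest, barcodes, template):
        bins = demultiplex_forward([make_read("r1", barcodes[0], template)], manifest)
        assert len(bins["S1"]) == 1
        # adaptor and barcode trimmed
        assert bins["S1"][0].bases.startswith(FWD_PRIMER.replace("Y", "T").replace("M", "A"))

    def test_single_error_goes_unassigned(self, manifest, barcodes, template):
        bad = "A" + barcodes[0][1:] if barcodes[0][0] != "A" else "C" + barcodes[0][1:]
        bins = demultiplex_forward([make_read("r1", bad, template)], manifest)
        assert len(bins["unassigned"]) == 1

    def test_empty_input(self, manifest):
        bins = demultiplex_forward([], manifest)
        assert all(len(v) == 0 for v in bins.values())

    def test_partition_property(self, manifest, barcodes, template):
        reads = [make_read(f"r{i}", barcodes[i % 4], template) for i in range(12)]
        bins = demultiplex_forward(reads, manifest)
        ids = [r.id for v in bins.values() for r in v]
        assert sorted(ids) == sorted(r.id for r in reads)
        assert len(set(ids)) == len(ids)


class TestDemultiplexReverse:
    def test_pair_maps_to_colony(self, manifest, barcodes, template):
        read = make_read("r1", barcodes[2], template, rev_barcode=barcodes[4])
        bins = demultiplex_forward([read], manifest)
        colonies = demultiplex_reverse(bins, manifest)
        assert len(colonies["C1"]) == 1 and len(colonies["C2"]) == 0
        assert colonies["C1"][0].bases == template  # fully trimmed

    def test_unknown_reverse_barcode_unassigned(self, manifest, barcodes, template):
        read = make_read("r1", barcodes[2], template, rev_barcode=barcodes[1])
        colonies = demultiplex_reverse(demultiplex_forward([read], manifest), manifest)
        assert len(colonies["unassigned"]) == 1

    def test_shared_forward_separated_by_reverse(self, manifest, barcodes, template):
        reads = [make_read("r1", barcodes[2], template, rev_barcode=barcodes[4]),
                 make_read("r2", barcodes[2], template, rev_barcode=barcodes[5])]
        colonies = demultiplex_reverse(demultiplex_forward(reads, manifest), manifest)
        assert [r.id for r in colonies["C1"]] == ["r1"]
        assert [r.id for r in colonies["C2"]] == ["r2"]


class TestQualityFilter:
    """Boundary semantics of the four rules, in their fixed order."""

    def _read(self, template, qual=38, primer=None):
        primer = primer or FWD_PRIMER.replace("Y", "T").replace("M", "A")
        bases = primer + template + reverse_complement(REV_PRIMER)
        return SequenceRecord("x", bases, [qual] * len(bases))

    def test_mean_quality_exactly_25_fails(self, template):
        _bio, reason = quality_filter(self._read(template, qual=25),
                                      FilterParams(), FWD_PRIMER, REV_PRIMER)
        assert reason == "quality"

    def test_mean_quality_just_above_passes(self, template):
        bio, reason = quality_filter(self._read(template, qual=26),
                                     FilterParams(), FWD_PRIMER, REV_PRIMER)
        assert reason is None and bio.bases == template

    def test_homopolymer_run_of_seven_fails(self, template):
        t = template[:100] + "AAAAAAA" + template[107:]
        assert longest_homopolymer(t) == 7
        _bio, reason = quality_filter(self._read(t), FilterParams(),
                                      FWD_PRIMER, REV_PRIMER)
        assert reason == "homopolymer"

    def test_run_of_six_passes(self):
        t = random_dna(np.random.default_rng(4), 100) + "GGGGGG" + \
            random_dna(np.random.default_rng(5), 100)
        t = t[:99] + "C" + t[100:]  # guard the junctions
        if longest_homopolymer(t) <= 6:
            _bio, reason = quality_filter(self._read(t), FilterParams(),
                                          FWD_PRIMER, REV_PRIMER)
            assert reason is None

    @pytest.mark.parametrize("length,expected", [(199, "length"), (200, None)])
    def test_length_boundary(self, length, expected):
        t = random_dna(np.random.default_rng(6), length)
        _bio, reason = quality_filter(self._read(t), FilterParams(),
                                      FWD_PRIMER, REV_PRIMER)
        assert reason == expected

    def test_primer_mismatch_fails(self, template):
        primer = "T" + FWD_PRIMER.replace("Y", "T").replace("M", "A")[1:]
        _bio, reason = quality_filter(self._read(template, primer=primer),
                                      FilterParams(), FWD_PRIMER, REV_PRIMER)
        assert reason == "primer"

    def test_missing_qualities_is_error(self, template):
        read = SequenceRecord("x", template)
        with pytest.raises(ValueError):
            quality_filter(read, FilterParams(), FWD_PRIMER, REV_PRIMER)

    def test_rule_order_quality_before_primer(self, template):
        primer = "T" + FWD_PRIMER.replace("Y", "T").replace("M", "A")[1:]
        _bio, reason = quality_filter(self._read(template, qual=10, primer=primer),
                                      FilterParams(), FWD_PRIMER, REV_PRIMER)
        assert reason == "quality"


class TestFilterLibrary:
    def _noise_free_library(self, manifest):
        profile = CommunityProfile({"T1": 1.0},
                                   {"T1": random_dna(np.random.default_rng(2), 280)})
        profiles = {e.sample_id: profile for e in manifest}
        return simulate_reads(profiles, manifest, NOISE_FREE, 15, seed=10)

    def test_full_retention_on_clean_reads(self, manifest):
        reads, _truth = self._noise_free_library(manifest)
        _clean, report = filter_library(reads, manifest)
        assert report.n_retained == report.n_input == len(reads)

    def test_report_reconciles(self, manifest, barcodes, template):
        reads = [make_read("good", barcodes[0], template),
                 make_read("lowq", barcodes[0], template, qual=20),
                 make_read("lost", "ACGTACGT", template)]
        _clean, report = filter_library(reads, manifest)
        assert report.n_retained + report.n_failed == report.n_input == 3
        assert report.failure_reasons().to_dict() == {"quality": 1, "barcode_unknown": 1}

    def test_filtering_idempotent(self, manifest, barcodes, template):
        reads = [make_read(f"r{i}", barcodes[0], template) for i in range(5)]
        clean, _ = filter_library(reads, manifest)
        # re-filtering the already-trimmed biological reads changes nothing
        params = FilterParams()
        for r in clean["S1"]:
            assert r.mean_quality() > params.min_mean_quality
            assert longest_homopolymer(r.bases) <= params.max_homopolymer
            assert len(r.bases) >= params.min_length
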