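"""Demultiplexing and quality filtering of barcoded amplicon reads.

Reads are assigned to samples by an exact match on the forward barcode
at its expected offset (after the sequencing adaptor); reads from picked
colonies additionally carry a reverse barcode at the 3' end whose
combination with the forward barcode uniquely identifies one colony.

Quality filtering applies four rules, evaluated in a fixed order so that
failure-reason accounting is reproducible:

1. quality      -- mean Phred score of the trimmed read must be > 25
                   (strictly; a mean of exactly 25.0 fails),
2. homopolymer  -- no single-base run longer than 6 nucleotides,
3. length       -- trimmed read length >= 200 bp,
4. primer       -- zero mismatches against the (IUPAC) forward primer.

The mean quality, homopolymer and length rules are evaluated on the
post-trim biological sequence (barcode, primers and, when present, the
reverse barcode removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .seq import SequenceRecord, iupac_mismatches, reverse_complement

__all__ = [
    "ManifestEntry",
    "SampleManifest",
    "FilterParams",
    "FilterReport",
    "demultiplex_forward",
    "demultiplex_reverse",
    "quality_filter",
    "filter_library",
    "DEFAULT_ADAPTOR",
]

# Titanium-style sequencing adaptor preceding the barcode on each read.
DEFAULT_ADAPTOR = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"

UNASSIGNED = "unassigned"

_MANIFEST_COLUMNS = [
    "sample_id", "fwd_barcode", "rev_barcode", "fwd_primer", "rev_primer",
    "sponge", "medium", "surface", "day", "colonies", "role", "plate_group",
]


@dataclass
class ManifestEntry:
    """One manifest row: a sample, an inoculum, or a single picked colony."""

    sample_id: str
    fwd_barcode: str
    fwd_primer: str
    rev_primer: str
    rev_barcode: str | None = None
    sponge: str = ""
    medium: str = ""
    surface: str = ""          # "agar" or "filter"
    day: int | None = None
    colonies: int | None = None  # visible colony count for scraped samples
    role: str = "scraped"      # inoculum | scraped | colony
    plate_group: str = ""      # groups colony rows sharing a forward barcode

    @property
    def is_inoculum(self) -> bool:
        return self.role == "inoculum"

    @property
    def demux_target(self) -> str:
        """Bin a forward-demultiplexed read lands in.

        Colony rows share a forward barcode per plate group; their reads
        first land in the plate-group bin and are split per colony by the
        reverse barcode.
        """
        return self.plate_group if self.role == "colony" else self.sample_id


class SampleManifest:
    """Barcode-and-primer bookkeeping mapping reads to samples and colonies."""

    def __init__(self, entries: Iterable[ManifestEntry]):
        self.entries: list[ManifestEntry] = list(entries)
        self._validate()

    def _validate(self) -> None:
        if not self.entries:
            raise ValueError("manifest has no entries")
        lengths = {len(e.fwd_barcode) for e in self.entries}
        if len(lengths) != 1:
            raise ValueError(f"forward barcodes have mixed lengths: {sorted(lengths)}")
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in manifest")
        fwd_target: dict[str, str] = {}
        for e in self.entries:
            tgt = e.demux_target
            if e.fwd_barcode in fwd_target and fwd_target[e.fwd_barcode] != tgt:
                raise ValueError(
                    f"forward barcode {e.fwd_barcode} maps to both "
                    f"{fwd_target[e.fwd_barcode]!r} and {tgt!r}"
                )
            fwd_target[e.fwd_barcode] = tgt
        pairs = [(e.fwd_barcode, e.rev_barcode) for e in self.entries if e.rev_barcode]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (forward, reverse) barcode pairs in manifest")
        colony_rev = [e for e in self.entries if e.role == "colony"]
        rev_lengths = {len(e.rev_barcode) for e in colony_rev if e.rev_barcode}
        if len(rev_lengths) > 1:
            raise ValueError("reverse barcodes have mixed lengths")
        for e in colony_rev:
            if not e.rev_barcode:
                raise ValueError(f"colony row {e.sample_id} lacks a reverse barcode")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0].fwd_barcode)

    def entry(self, sample_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)

    def forward_map(self) -> dict[str, str]:
        """fwd_barcode -> demux target (sample id or plate group)."""
        return {e.fwd_barcode: e.demux_target for e in self.entries}

    def colony_map(self, plate_group: str) -> dict[str, str]:
        """reverse barcode -> colony id for one plate group."""
        return {
            e.rev_barcode: e.sample_id
            for e in self.entries
            if e.role == "colony" and e.plate_group == plate_group
        }

    def targets(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.demux_target not in out:
                out.append(e.demux_target)
        return out

    def metadata_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(e) for e in self.entries])
        return df.set_index("sample_id")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame([vars(e) for e in self.entries])[_MANIFEST_COLUMNS]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleManifest":
        df = pd.read_csv(path, sep="\t", dtype={"fwd_barcode": str, "rev_barcode": str})
        entries = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            for key in ("rev_barcode", "sponge", "medium", "surface", "plate_group", "role"):
                if key in d and (pd.isna(d[key]) or d[key] == ""):
                    d[key] = None if key == "rev_barcode" else ""
            for key in ("day", "colonies"):
                d[key] = None if pd.isna(d.get(key)) else int(d[key])
            if not d.get("role"):
                d["role"] = "scraped"
            entries.append(ManifestEntry(**d))
        return cls(entries)


@dataclass(frozen=True)
class FilterParams:
    """Quality-filter thresholds (defaults: mean Q > 25, runs <= 6,
    length >= 200, zero primer mismatches)."""

    min_mean_quality: float = 25.0   # exclusive
    max_homopolymer: int = 6
    min_length: int = 200
    max_primer_mismatches: int = 0

    def __post_init__(self) -> None:
        if min(self.min_mean_quality, self.max_homopolymer,
               self.min_length, self.max_primer_mismatches) < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class FilterReport:
    """Per-read filtering decisions plus per-target retention counts."""

    rows: pd.DataFrame  # columns: read_id, target, decision, reason

    @property
    def n_input(self) -> int:
        return len(self.rows)

    @property
    def n_retained(self) -> int:
        return int((self.rows["decision"] == "pass").sum())

    @property
    def n_failed(self) -> int:
        return self.n_input - self.n_retained

    def retained_counts(self) -> pd.Series:
        ok = self.rows[self.rows["decision"] == "pass"]
        return ok.groupby("target").size()

    def failure_reasons(self) -> pd.Series:
        bad = self.rows[self.rows["decision"] == "fail"]
        return bad.groupby("reason").size()

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def longest_homopolymer(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best if seq else 0


def _find_reverse_primer(bases: str, rev_primer: str) -> int | None:
    """Rightmost exact (IUPAC) occurrence of the reverse-complemented
    reverse primer, or None when the read does not reach it."""
    pat = reverse_complement(rev_primer)
    L = len(pat)
    for start in range(len(bases) - L, -1, -1):
        if iupac_mismatches(pat, bases[start : start + L]) == 0:
            return start
    return None


def split_read(read: SequenceRecord, fwd_primer: str, rev_primer: str | None):
    """Split a barcode-trimmed read into (biological record, 3' tail).

    The biological record is the read minus the forward-primer prefix and,
    when the read reaches the reverse primer, minus the reverse primer and
    everything after it.  The tail is whatever follows the reverse primer
    (the reverse-complemented reverse barcode, for colony reads).
    """
    tail = ""
    stop = len(read.bases)
    if rev_primer:
        hit = _find_reverse_primer(read.bases, rev_primer)
        if hit is not None and hit > len(fwd_primer):
            tail = read.bases[hit + len(rev_primer):]
            stop = hit
    bio = read.slice(len(fwd_primer), stop)
    return bio, tail


def demultiplex_forward(
    reads: Iterable[SequenceRecord],
    manifest: SampleManifest,
    adaptor: str = DEFAULT_ADAPTOR,
) -> dict[str, list[SequenceRecord]]:
    """Bin reads by exact forward-barcode match at its expected offset.

    Returns a dict mapping each demux target (sample id or colony plate
    group) to its reads, with adaptor and barcode trimmed, plus an
    ``"unassigned"`` bin.  Each read lands in exactly one bin.
    """
    fwd = manifest.forward_map()
    blen = manifest.barcode_length
    off = len(adaptor)
    bins: dict[str, list[SequenceRecord]] = {t: [] for t in manifest.targets()}
    bins[UNASSIGNED] = []
    for read in reads:
        barcode = read.bases[off : off + blen]
        target = fwd.get(barcode)
        if target is None or len(barcode) < blen:
            bins[UNASSIGNED].append(read)
        else:
            bins[target].append(read.slice(off + blen, len(read.bases)))
    return bins


def demultiplex_reverse(
    plate_reads: dict[str, list[SequenceRecord]] | list[SequenceRecord],
    manifest: SampleManifest,
    plate_group: str | None = None,
) -> dict[str, list[SequenceRecord]]:
    """Split forward-demultiplexed colony-plate reads by reverse barcode.

    Accepts either a single plate group's read list (with ``plate_group``
    given) or the forward-demux bin dict.  Reads whose 3' tail does not
    carry a known reverse barcode go to ``"unassigned"``.  Matched reads
    are trimmed of the reverse primer and barcode (the returned records
    are the biological sequence minus the forward primer as well).
    """
    if isinstance(plate_reads, list):
        if plate_group is None:
            raise ValueError("plate_group required when passing a read list")
        groups = {plate_group: plate_reads}
    else:
        colony_groups = {e.plate_group for e in manifest.entries if e.role == "colony"}
        groups = {g: r for g, r in plate_reads.items() if g in colony_groups}

    out: dict[str, list[SequenceRecord]] = {UNASSIGNED: []}
    for group, reads in groups.items():
        rev_map = manifest.colony_map(group)
        if not rev_map:
            raise ValueError(f"plate group {group!r} has no colony entries")
        entry = next(e for e in manifest.entries
                     if e.role == "colony" and e.plate_group == group)
        bc_len = len(entry.rev_barcode)
        for cid in rev_map.values():
            out.setdefault(cid, [])
        for read in reads:
            bio, tail = split_read(read, entry.fwd_primer, entry.rev_primer)
            barcode = reverse_complement(tail[:bc_len]) if len(tail) >= bc_len else ""
            cid = rev_map.get(barcode)
            if cid is None:
                out[UNASSIGNED].append(read)
            else:
                out[cid].append(bio)
    return out


def quality_filter(
    read: SequenceRecord,
    params: FilterParams,
    primer: str,
    rev_primer: str | None = None,
):
    """Apply the four filtering rules to one barcode-trimmed read.

    Returns ``(trimmed_record, None)`` on pass or ``(None, reason)`` on
    the first failing rule, in the order quality, homopolymer, length,
    primer.
    """
    if read.quality is None:
        raise ValueError(f"read {read.id!r} has no quality scores")
    bio, _tail = split_read(read, primer, rev_primer)
    if len(bio.bases) == 0 or bio.mean_quality() <= params.min_mean_quality:
        return None, "quality"
    if longest_homopolymer(bio.bases) > params.max_homopolymer:
        return None, "homopolymer"
    if len(bio.bases) < params.min_length:
        return None, "length"
    prefix = read.bases[: len(primer)]
    if len(prefix) < len(primer) or iupac_mismatches(primer, prefix) > params.max_primer_mismatches:
        return None, "primer"
    return bio, None


def filter_library(
    reads: Iterable[SequenceRecord],
    manifest: SampleManifest,
    params: FilterParams = FilterParams(),
    adaptor: str = DEFAULT_ADAPTOR,
) -> tuple[dict[str, list[SequenceRecord]], FilterReport]:
    """Demultiplex and quality-filter a whole library.

    Returns clean, fully trimmed reads per sample (and per colony, for
    double-barcoded plate groups) and a :class:`FilterReport` whose rows
    reconcile exactly with the input (retained + failed == input).
    """
    reads = list(reads)
    bins = demultiplex_forward(reads, manifest, adaptor)
    colony_groups = {e.plate_group for e in manifest.entries if e.role == "colony"}
    entries_by_target = {}
    for e in manifest.entries:
        entries_by_target.setdefault(e.demux_target, e)

    clean: dict[str, list[SequenceRecord]] = {}
    rows = []
    for read in bins[UNASSIGNED]:
        rows.append((read.id, UNASSIGNED, "fail", "barcode_unknown"))
    for target, target_reads in bins.items():
        if target == UNASSIGNED:
            continue
        entry = entries_by_target[target]
        is_colony_group = target in colony_groups
        rev_map = manifest.colony_map(target) if is_colony_group else {}
        bc_len = len(next(iter(rev_map))) if rev_map else 0
        for read in target_reads:
            bio, reason = quality_filter(read, params, entry.fwd_primer, entry.rev_primer)
            if reason is not None:
                rows.append((read.id, target, "fail", reason))
                continue
            final_target = target
            if is_colony_group:
                _bio, tail = split_read(read, entry.fwd_primer, entry.rev_primer)
                barcode = reverse_complement(tail[:bc_len]) if len(tail) >= bc_len else ""
                cid = rev_map.get(barcode)
                if cid is None:
                    rows.append((read.id, target, "fail", "barcode_unknown"))
                    continue
                final_target = cid
            clean.setdefault(final_target, []).append(bio)
            rows.append((read.id, final_target, "pass", ""))

    report = FilterReport(
        pd.DataFrame(rows, columns=["read_id", "target", "decision", "reason"])
    )
    return clean, report
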