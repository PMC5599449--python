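"""Synthetic cultivation-experiment data with known ground truth.

This module generates every input the downstream analysis consumes:
a mock type-strain reference database, sponge-like source communities,
plating outcomes (scraped plate communities with inoculum carry-over and
a dominant fast-growing spike-in, plus individually picked colonies),
and error-bearing barcoded pyrosequencing-style reads of a ~311 bp
V1-V2 amplicon — all byte-reproducible given a seed, with a
:class:`GroundTruth` object recording what actually happened so every
pipeline stage can be scored.

The generator deliberately reproduces the failure modes that motivate
the analysis criteria: cells carried over from the inoculum appear in
scraped communities without having grown, and one designated
*Pseudovibrio*-like fast grower absent from the source communities
dominates the plates.

Reference sequences are random with constrained composition (45-55% GC)
rather than real 16S genes, which keeps the package download-free; any
real reference FASTA + taxonomy TSV can be supplied instead via
:meth:`ReferenceDb.read`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .demux import DEFAULT_ADAPTOR, ManifestEntry, SampleManifest
from .seq import SequenceRecord, percent_identity, reverse_complement, write_fasta, read_fasta

__all__ = [
    "ReferenceDb",
    "CommunityProfile",
    "NovelSpec",
    "PlatingScenario",
    "PlatingTruth",
    "GroundTruth",
    "ErrorModel",
    "NOISE_FREE",
    "generate_reference_db",
    "mutate_to_divergence",
    "simulate_community",
    "simulate_plating",
    "simulate_colony_pick",
    "simulate_reads",
    "sample_otu_counts",
    "planted_violation_reads",
    "generate_barcodes",
    "SimulationScenario",
    "design_plating_scenario",
    "SimulationResult",
    "demo_scenario",
    "study_scenario",
    "run_simulation",
    "FWD_PRIMER",
    "REV_PRIMER",
]

# Degenerate forward primer (27F-DegS-like) and reverse primer (338R-like)
# bracketing the V1-V2 region.
FWD_PRIMER = "AGAGTTTGATYMTGGCTCAG"
REV_PRIMER = "GCTGCCTCCCGTAGGAGT"

_BASES = np.array(list("ACGT"))
_IUPAC_CHOICES = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _subseed(seed: int, *salt: int) -> int:
    """Derive a child seed < 2**31 from a parent seed and salts."""
    x = np.random.SeedSequence([int(seed) % (2**31), *[int(s) % (2**31) for s in salt]])
    return int(x.generate_state(1)[0] % (2**31))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5,
                max_run: int = 4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = list(rng.choice(_BASES, size=length, p=p))
    # Cap homopolymer runs so simulated templates never trip the
    # homopolymer filter by accident.
    run = 1
    for i in range(1, length):
        run = run + 1 if bases[i] == bases[i - 1] else 1
        if run > max_run:
            alternatives = [b for b in "ACGT" if b != bases[i]]
            bases[i] = alternatives[int(rng.integers(len(alternatives)))]
            run = 1
    return "".join(bases)


def _realize_primer(primer: str, rng: np.random.Generator) -> str:
    """Draw one concrete oligo from a degenerate primer pattern."""
    out = []
    for ch in primer:
        if ch in _IUPAC_CHOICES:
            opts = _IUPAC_CHOICES[ch]
            out.append(opts[int(rng.integers(len(opts)))])
        else:
            out.append(ch)
    return "".join(out)


def generate_barcodes(n: int, rng: np.random.Generator, length: int = 8,
                      min_dist: int = 3, max_tries: int = 100_000) -> list[str]:
    """Random fixed-length barcodes with pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not find {n} barcodes at distance {min_dist}")
        cand = "".join(rng.choice(_BASES, size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_dist for bc in out):
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------

_PHYLA = ["Proteobacteria", "Actinobacteria", "Bacteroidetes",
          "Firmicutes", "Chloroflexi", "Acidobacteria"]


@dataclass
class ReferenceDb:
    """Mock type-strain 16S database with a designated V1-V2 window.

    ``records`` hold full-length (~1500 bp) sequences; ``v1v2_span`` is
    the 0-based half-open window the amplicon covers, shared by all
    records.  ``taxonomy`` maps each id to a 6-rank lineage string
    (phylum; class; order; family; genus; species).
    """

    records: list[SequenceRecord]
    taxonomy: dict[str, str]
    v1v2_span: tuple[int, int] = (20, 331)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in reference database")
        missing = [i for i in ids if i not in self.taxonomy]
        if missing:
            raise ValueError(f"records without taxonomy: {missing}")
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, rid: str) -> SequenceRecord:
        return self._by_id[rid]

    def v1v2(self, rid: str) -> str:
        s, e = self.v1v2_span
        return self._by_id[rid].bases[s:e]

    def write(self, fasta_path, taxonomy_path) -> None:
        write_fasta(self.records, fasta_path)
        with open(taxonomy_path, "w") as fh:
            fh.write("id\tlineage\tv1v2_start\tv1v2_end\n")
            s, e = self.v1v2_span
            for r in self.records:
                fh.write(f"{r.id}\t{self.taxonomy[r.id]}\t{s}\t{e}\n")

    @classmethod
    def read(cls, fasta_path, taxonomy_path) -> "ReferenceDb":
        records = read_fasta(fasta_path)
        taxonomy = {}
        span = None
        with open(taxonomy_path) as fh:
            header = fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                taxonomy[parts[0]] = parts[1]
                if len(parts) >= 4:
                    span = (int(parts[2]), int(parts[3]))
        return cls(records, taxonomy, span or (0, len(records[0].bases)))


def _lineage(i: int) -> str:
    phylum = _PHYLA[(i // 8) % len(_PHYLA)]
    return (
        f"p__{phylum}; c__{phylum}_cl{i // 8 + 1}; o__Order{i // 4 + 1}; "
        f"f__Family{i // 2 + 1}; g__Genus{i + 1}; s__Typestrain{i + 1:03d}"
    )


def generate_reference_db(
    n_types: int,
    seed: int,
    full_length: int = 1500,
    v1v2_span: tuple[int, int] = (20, 331),
    max_window_identity: float = 90.0,
) -> ReferenceDb:
    """Generate mutually dissimilar mock type strains, deterministically.

    Any two generated type strains are < ``max_window_identity`` percent
    identical over the V1-V2 window.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    rng = np.random.default_rng(seed)
    s, e = v1v2_span
    records: list[SequenceRecord] = []
    windows: list[str] = []
    for i in range(n_types):
        for _attempt in range(50):
            gc = float(rng.uniform(0.45, 0.55))
            seq = _random_seq(rng, full_length, gc)
            win = seq[s:e]
            if all(percent_identity(win, w) < max_window_identity for w in windows):
                break
        else:
            raise RuntimeError("could not generate a sufficiently dissimilar type strain")
        records.append(SequenceRecord(f"TS{i + 1:04d}", seq))
        windows.append(win)
    taxonomy = {r.id: _lineage(i) for i, r in enumerate(records)}
    return ReferenceDb(records, taxonomy, v1v2_span)


def mutate_to_divergence(
    parent: SequenceRecord,
    target_percent: float,
    seed: int,
    new_id: str | None = None,
    tolerance: float = 0.5,
    max_iter: int = 500,
) -> SequenceRecord:
    """Substitute bases until identity to the parent is 100 - target +/- 0.5.

    Substitution-only mutation keeps the divergence interpretable as
    fraction of differing sites; achieved divergence is verified with
    :func:`percent_identity` and adjusted until within tolerance.
    """
    if not 0 <= target_percent <= 25:
        raise ValueError("target divergence must be in [0, 25] percent")
    rng = np.random.default_rng(seed)
    L = len(parent.bases)
    target_identity = 100.0 - target_percent
    seq = list(parent.bases)
    mutated: list[int] = []

    def mutate_one() -> bool:
        free = [i for i in range(L) if i not in set(mutated)]
        if not free:
            return False
        pos = int(rng.choice(free))
        alternatives = [b for b in "ACGT" if b != parent.bases[pos]]
        seq[pos] = alternatives[int(rng.integers(3))]
        mutated.append(pos)
        return True

    k = int(round(target_percent / 100.0 * L))
    for _ in range(k):
        mutate_one()
    for _ in range(max_iter):
        ident = percent_identity(parent.bases, "".join(seq))
        if abs(ident - target_identity) <= tolerance:
            break
        if ident > target_identity:
            if not mutate_one():
                raise ValueError("target divergence unreachable for this length")
        else:
            pos = mutated.pop()
            seq[pos] = parent.bases[pos]
    else:
        raise ValueError("target divergence unreachable for this length")
    return SequenceRecord(new_id or f"{parent.id}_div{target_percent:g}", "".join(seq))


# ---------------------------------------------------------------------------
# Communities and plating
# ---------------------------------------------------------------------------


@dataclass
class NovelSpec:
    """A community member engineered to diverge from its parent type strain."""

    divergence: float                 # percent divergence in the V1-V2 window
    abundance: float | None = None    # fixed relative abundance, or lognormal draw
    parent_id: str | None = None


@dataclass
class CommunityProfile:
    """Relative-abundance profile plus V1-V2 templates for read simulation."""

    abundances: dict[str, float]
    templates: dict[str, str]
    novel_members: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")
        for t in self.abundances:
            if t not in self.templates:
                raise ValueError(f"taxon {t!r} has no template")
        for t, (_parent, div) in self.novel_members.items():
            if not 0 <= div <= 25:
                raise ValueError(f"novel member {t!r}: divergence {div} out of [0, 25]")


def simulate_community(
    refdb: ReferenceDb,
    n_taxa: int,
    lognormal_params: tuple[float, float] = (0.0, 1.0),
    novel_spec: list[NovelSpec] = (),
    seed: int = 0,
    exclude: set[str] = frozenset(),
) -> CommunityProfile:
    """Draw a lognormal-abundance community from the reference database.

    ``novel_spec`` members are created by :func:`mutate_to_divergence`
    from reference parents and included as additional taxa; ``exclude``
    keeps listed reference ids out of the community (e.g. the parent of
    a plate-only spike-in).
    """
    rng = np.random.default_rng(seed)
    available = [r for r in refdb.ids if r not in exclude]
    if n_taxa > len(available):
        raise ValueError(f"n_taxa={n_taxa} exceeds available references ({len(available)})")
    chosen = [available[i] for i in rng.choice(len(available), size=n_taxa, replace=False)]
    templates = {t: refdb.v1v2(t) for t in chosen}
    novel_members: dict[str, tuple[str, float]] = {}
    fixed: dict[str, float] = {}
    taxa = list(chosen)
    for i, spec in enumerate(novel_spec):
        parent = spec.parent_id or chosen[int(rng.integers(len(chosen)))]
        nid = f"novel{i + 1}"
        parent_window = SequenceRecord(parent, refdb.v1v2(parent))
        child = mutate_to_divergence(parent_window, spec.divergence,
                                     _subseed(seed, 7001, i), new_id=nid)
        templates[nid] = child.bases
        novel_members[nid] = (parent, spec.divergence)
        taxa.append(nid)
        if spec.abundance is not None:
            fixed[nid] = spec.abundance
    mu, sigma = lognormal_params
    draws = rng.lognormal(mu, sigma, size=len(taxa))
    free = [t for t in taxa if t not in fixed]
    free_total = 1.0 - sum(fixed.values())
    if free_total <= 0:
        raise ValueError("fixed novel abundances sum to >= 1")
    weights = {t: d for t, d in zip(taxa, draws) if t in set(free)}
    wsum = sum(weights.values())
    abundances = {t: fixed.get(t, weights.get(t, 0.0) / wsum * free_total) for t in taxa}
    # exact renormalisation against floating-point drift
    total = sum(abundances.values())
    abundances = {t: a / total for t, a in abundances.items()}
    return CommunityProfile(abundances, templates, novel_members)


@dataclass
class PlatingScenario:
    """How an inoculated plate behaves: who grows, who dominates, and how
    much un-grown inoculum material is carried into the scraped sample."""

    growth_prob: dict[str, float]
    dominance_factor: float = 1.0
    dominant_taxon: str | None = None
    spike_in: dict[str, tuple[str, float]] = field(default_factory=dict)  # id -> (template, weight)
    carryover_reads_fraction: float = 0.0
    n_visible_colonies: int = 100
    pick_cap_per_taxon: int = 3

    def __post_init__(self) -> None:
        for t, p in self.growth_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"growth probability for {t!r} out of [0, 1]")
        if not 0 <= self.carryover_reads_fraction <= 1:
            raise ValueError("carryover_reads_fraction out of [0, 1]")


@dataclass
class PlatingTruth:
    """What truly happened on one plate."""

    grown: set[str]
    colony_mixture: dict[str, float]
    n_visible_colonies: int


def _colony_weights(profile: CommunityProfile, scenario: PlatingScenario) -> dict[str, float]:
    w: dict[str, float] = {}
    for t, a in profile.abundances.items():
        p = scenario.growth_prob.get(t, 0.0)
        if p > 0:
            w[t] = a * p
    for t, (_template, base_weight) in scenario.spike_in.items():
        p = scenario.growth_prob.get(t, 1.0)
        if base_weight * p > 0:
            w[t] = base_weight * p
    if scenario.dominant_taxon is not None and scenario.dominant_taxon in w:
        w[scenario.dominant_taxon] *= scenario.dominance_factor
    return w


def simulate_plating(
    profile: CommunityProfile,
    scenario: PlatingScenario,
    seed: int = 0,
) -> tuple[CommunityProfile, PlatingTruth]:
    """Deterministic plating outcome for one plate.

    The scraped composition is ``(1 - carryover) * colony_mixture +
    carryover * inoculum``, with the colony mixture weighted by growth
    probability and the dominance factor.  Taxa with growth probability
    zero appear only through carry-over and are recorded as not grown.
    """
    c = scenario.carryover_reads_fraction
    w = _colony_weights(profile, scenario)
    total = sum(w.values())
    if total == 0 and c == 0:
        raise ValueError("nothing grows and there is no carry-over: empty plate")
    mix = {t: v / total for t, v in w.items()} if total > 0 else {}
    grown = set(w)
    scraped: dict[str, float] = {}
    for t in set(mix) | set(profile.abundances):
        a = (1 - c) * mix.get(t, 0.0) + c * profile.abundances.get(t, 0.0)
        if a > 0:
            scraped[t] = a
    templates = dict(profile.templates)
    for t, (template, _w) in scenario.spike_in.items():
        templates[t] = template
    total = sum(scraped.values())
    scraped = {t: a / total for t, a in scraped.items()}
    novel = {t: v for t, v in profile.novel_members.items() if t in scraped}
    scraped_profile = CommunityProfile(scraped, templates, novel)
    return scraped_profile, PlatingTruth(grown, mix, scenario.n_visible_colonies)


def simulate_colony_pick(
    profile: CommunityProfile,
    scenario: PlatingScenario,
    n_colonies: int,
    seed: int = 0,
    id_prefix: str = "colony",
) -> list[tuple[str, str]]:
    """Pick colonies proportionally to growth-weighted abundance.

    At most ``scenario.pick_cap_per_taxon`` colonies of the same taxon
    are picked per plate (pickers stop picking a morphology they already
    have); fewer than ``n_colonies`` may be returned when every growing
    taxon is at its cap.
    """
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    rng = np.random.default_rng(seed)
    w = _colony_weights(profile, scenario)
    if not w or n_colonies == 0:
        return []
    taxa = sorted(w)
    probs = np.array([w[t] for t in taxa])
    probs = probs / probs.sum()
    picked: list[tuple[str, str]] = []
    counts: dict[str, int] = {}
    attempts = 0
    while len(picked) < n_colonies and attempts < 50 * n_colonies + 100:
        attempts += 1
        t = taxa[int(rng.choice(len(taxa), p=probs))]
        if counts.get(t, 0) >= scenario.pick_cap_per_taxon:
            if all(counts.get(x, 0) >= scenario.pick_cap_per_taxon for x in taxa):
                break
            continue
        counts[t] = counts.get(t, 0) + 1
        picked.append((f"{id_prefix}{len(picked) + 1:03d}", t))
    return picked


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass
class ErrorModel:
    """454-like per-read error model.

    Substitutions are uniform over alternative bases at
    ``substitution_rate`` per base.  Homopolymer runs shrink or grow by
    one base with probability proportional to run length
    (``homopolymer_indel_rate`` per run base), mimicking pyrosequencing
    flow miscalls.  Qualities come from a two-state (good/bad) profile.
    """

    substitution_rate: float = 0.003
    homopolymer_indel_rate: float = 0.003
    bad_segment_prob: float = 0.02
    good_quality: tuple[float, float] = (38.0, 2.0)
    bad_quality: tuple[float, float] = (14.0, 4.0)

    def corrupt(self, seq: str, rng: np.random.Generator) -> tuple[str, int, int]:
        """Return (corrupted sequence, n substitutions, n homopolymer indels)."""
        n_sub = 0
        if self.substitution_rate > 0:
            chars = list(seq)
            hits = np.flatnonzero(rng.random(len(chars)) < self.substitution_rate)
            for i in hits:
                alternatives = [b for b in "ACGT" if b != chars[i]]
                chars[i] = alternatives[int(rng.integers(3))]
                n_sub += 1
            seq = "".join(chars)
        n_indel = 0
        if self.homopolymer_indel_rate > 0:
            out = []
            i = 0
            while i < len(seq):
                j = i
                while j < len(seq) and seq[j] == seq[i]:
                    j += 1
                run = j - i
                newrun = run
                if rng.random() < min(0.5, self.homopolymer_indel_rate * run):
                    if run == 1 or rng.random() < 0.5:
                        newrun = run + 1
                    else:
                        newrun = run - 1
                    n_indel += 1
                out.append(seq[i] * newrun)
                i = j
            seq = "".join(out)
        return seq, n_sub, n_indel

    def qualities(self, n: int, rng: np.random.Generator) -> list[int]:
        bad = rng.random(n) < self.bad_segment_prob
        mu = np.where(bad, self.bad_quality[0], self.good_quality[0])
        sd = np.where(bad, self.bad_quality[1], self.good_quality[1])
        q = rng.normal(mu, sd)
        return [int(x) for x in np.clip(np.rint(q), 2, 40)]


NOISE_FREE = ErrorModel(0.0, 0.0, 0.0)


@dataclass
class GroundTruth:
    """Per-sample, per-colony and per-read provenance of a simulation."""

    sample_composition: dict[str, dict[str, float]] = field(default_factory=dict)
    colony_taxon: dict[str, str] = field(default_factory=dict)
    read_sample: dict[str, str] = field(default_factory=dict)
    read_taxon: dict[str, str] = field(default_factory=dict)
    read_errors: dict[str, tuple[int, int]] = field(default_factory=dict)
    grown: dict[str, list[str]] = field(default_factory=dict)
    novel_members: dict[str, list] = field(default_factory=dict)  # taxon -> [parent, divergence]
    templates: dict[str, str] = field(default_factory=dict)
    expected_filter: dict[str, str] = field(default_factory=dict)
    visible_colonies: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["read_errors"] = {k: list(v) for k, v in self.read_errors.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["read_errors"] = {k: tuple(v) for k, v in d.get("read_errors", {}).items()}
        d["novel_members"] = {k: [v[0], float(v[1])] for k, v in d.get("novel_members", {}).items()}
        return cls(**d)


def simulate_reads(
    profiles: dict[str, CommunityProfile],
    manifest: SampleManifest,
    error_model: ErrorModel,
    n_reads: int | dict[str, int],
    seed: int = 0,
    adaptor: str = DEFAULT_ADAPTOR,
    truth: GroundTruth | None = None,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Emit barcoded, error-bearing FASTQ-style reads for every manifest entry.

    Each read is adaptor + forward barcode + forward primer + template
    (+ reverse-complemented reverse primer, + reverse-complemented
    reverse barcode for colony entries), corrupted by the error model,
    with per-read provenance recorded in the returned ground truth.
    """
    truth = truth or GroundTruth()
    reads: list[SequenceRecord] = []
    counter = len(truth.read_sample)
    for entry in manifest:
        if entry.sample_id not in profiles:
            continue
        profile = profiles[entry.sample_id]
        n = n_reads if isinstance(n_reads, int) else n_reads.get(entry.sample_id, 0)
        rng = np.random.default_rng(_subseed(seed, 1301, counter, len(entry.sample_id)))
        taxa = sorted(profile.abundances)
        probs = np.array([profile.abundances[t] for t in taxa])
        probs = probs / probs.sum()
        truth.sample_composition[entry.sample_id] = dict(
            zip(taxa, (float(p) for p in probs))
        )
        for t, tpl in profile.templates.items():
            truth.templates.setdefault(t, tpl)
        for t, v in profile.novel_members.items():
            truth.novel_members.setdefault(t, [v[0], float(v[1])])
        for _ in range(n):
            counter += 1
            taxon = taxa[int(rng.choice(len(taxa), p=probs))]
            template = profile.templates[taxon]
            parts = [adaptor, entry.fwd_barcode, _realize_primer(entry.fwd_primer, rng),
                     template, reverse_complement(_realize_primer(entry.rev_primer, rng))]
            if entry.role == "colony" and entry.rev_barcode:
                parts.append(reverse_complement(entry.rev_barcode))
            raw = "".join(parts)
            corrupted, n_sub, n_indel = error_model.corrupt(raw, rng)
            rid = f"r{counter:07d}"
            reads.append(SequenceRecord(rid, corrupted,
                                        error_model.qualities(len(corrupted), rng)))
            truth.read_sample[rid] = entry.sample_id
            truth.read_taxon[rid] = taxon
            truth.read_errors[rid] = (n_sub, n_indel)
    return reads, truth


def sample_otu_counts(
    profile: CommunityProfile, depth: int, rng: np.random.Generator
) -> dict[str, int]:
    """Multinomial read counts at a given depth — the counts-level fast
    path that skips sequence simulation entirely."""
    taxa = sorted(profile.abundances)
    probs = np.array([profile.abundances[t] for t in taxa])
    draws = rng.multinomial(depth, probs / probs.sum())
    return {t: int(c) for t, c in zip(taxa, draws) if c > 0}


# ---------------------------------------------------------------------------
# Planted filter violations (per-read ground truth for the filter rules)
# ---------------------------------------------------------------------------

_VIOLATION_KINDS = [
    "pass", "quality_below", "quality_boundary", "homopolymer",
    "length_short", "length_boundary", "primer_mismatch",
]

_EXPECTED = {
    "pass": "pass",
    "quality_below": "quality",
    "quality_boundary": "quality",   # mean exactly 25.0 fails the strict > 25 rule
    "homopolymer": "homopolymer",
    "length_short": "length",
    "length_boundary": "pass",       # exactly 200 bp passes the >= 200 rule
    "primer_mismatch": "primer",
}


def planted_violation_reads(
    entry: ManifestEntry,
    n_reads: int,
    seed: int,
    adaptor: str = DEFAULT_ADAPTOR,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Reads that each violate exactly one filter rule (or none).

    Cycles through: clean pass, mean quality below 25, mean quality
    exactly 25.0 (boundary, fails), a 7-base homopolymer run, trimmed
    length 199 (fails) and exactly 200 (passes), and one substitution in
    the forward primer.  Returns the reads and the expected per-read
    decision ("pass" or the failure reason).
    """
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    expected: dict[str, str] = {}
    for i in range(n_reads):
        kind = _VIOLATION_KINDS[i % len(_VIOLATION_KINDS)]
        length = 260
        if kind == "length_short":
            length = 199
        elif kind == "length_boundary":
            length = 200
        template = _random_seq(rng, length)
        if kind == "homopolymer":
            pos = int(rng.integers(20, length - 30))
            base = template[pos]
            left = template[pos - 1]
            run_base = next(b for b in "ACGT" if b not in (base, left, template[pos + 7]))
            template = template[:pos] + run_base * 7 + template[pos + 7:]
        primer = _realize_primer(entry.fwd_primer, rng)
        if kind == "primer_mismatch":
            plain = [j for j, ch in enumerate(entry.fwd_primer) if ch in "ACGT"]
            pos = plain[int(rng.integers(len(plain)))]
            alternatives = [b for b in "ACGT" if b != primer[pos]]
            primer = primer[:pos] + alternatives[int(rng.integers(3))] + primer[pos + 1:]
        raw = (adaptor + entry.fwd_barcode + primer + template
               + reverse_complement(_realize_primer(entry.rev_primer, rng)))
        if kind == "quality_below":
            quals = [20] * len(raw)
        elif kind == "quality_boundary":
            quals = [25] * len(raw)
        else:
            quals = [38] * len(raw)
        rid = f"v{i + 1:06d}"
        reads.append(SequenceRecord(rid, raw, quals))
        expected[rid] = _EXPECTED[kind]
    return reads, expected


# ---------------------------------------------------------------------------
# Whole-experiment scenarios
# ---------------------------------------------------------------------------


@dataclass
class SimulationScenario:
    """Shape and parameters of a full simulated cultivation experiment.

    The default (:func:`study_scenario`) mirrors the study design: three
    sponge sources, five media, agar and filter surfaces, two harvest
    days for plate scraping, and a set of antibiotic plate groups for
    colony picking.  :func:`demo_scenario` is the scaled-down version
    used in tests and examples.
    """

    sponges: list[str] = field(default_factory=lambda: ["AA", "PF", "CC"])
    media: list[str] = field(default_factory=lambda: ["Ma", "Ma10", "MH", "MH10", "Mu"])
    surfaces: list[str] = field(default_factory=lambda: ["agar", "filter"])
    days: list[int] = field(default_factory=lambda: [15, 30])
    antibiotic_groups: int = 13
    colonies_per_plate: int = 8
    n_reference_types: int = 16
    n_taxa_per_sponge: int = 9
    novel_divergences: list[float] = field(default_factory=lambda: [5.0, 11.0, 18.0])
    novel_abundance: float = 0.004
    n_growers: int = 5
    dominant_share: float = 0.55
    dominant_divergence: float = 4.0
    carryover_reads_fraction: float = 0.03
    reads_per_sample: int = 200
    reads_per_colony: int = 30
    error_model: ErrorModel = field(default_factory=ErrorModel)
    lognormal_sigma: float = 1.0

    def sample_grid(self) -> list[tuple[str, str, str, int]]:
        return [(sp, m, su, d) for sp in self.sponges for m in self.media
                for su in self.surfaces for d in self.days]


def study_scenario(**overrides) -> SimulationScenario:
    """Full study-shaped scenario: 60 scraped samples + 3 inocula + 13
    antibiotic plate groups."""
    return SimulationScenario(**overrides)


def demo_scenario(**overrides) -> SimulationScenario:
    """Scaled-down scenario for tests and the worked example."""
    defaults = dict(
        media=["Ma", "MH"],
        surfaces=["agar"],
        days=[15],
        antibiotic_groups=2,
        colonies_per_plate=6,
        n_reference_types=12,
        n_taxa_per_sponge=7,
        reads_per_sample=120,
        reads_per_colony=20,
    )
    defaults.update(overrides)
    return SimulationScenario(**defaults)


@dataclass
class SimulationResult:
    """Everything one simulated experiment produced."""

    refdb: ReferenceDb
    manifest: SampleManifest
    reads: list[SequenceRecord]
    truth: GroundTruth
    profiles: dict[str, CommunityProfile]
    plating: dict[str, PlatingScenario]
    scenario: SimulationScenario

    def write(self, outdir) -> None:
        from .seq import write_fastq

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq(self.reads, outdir / "reads.fastq")
        self.manifest.to_tsv(outdir / "manifest.tsv")
        self.refdb.write(outdir / "reference.fasta", outdir / "taxonomy.tsv")
        self.truth.to_json(outdir / "ground_truth.json")


def design_plating_scenario(
    profile: CommunityProfile,
    scenario: SimulationScenario,
    refdb: ReferenceDb,
    dominant_template: str,
    seed: int,
    n_visible_colonies: int,
) -> PlatingScenario:
    """Choose growers and growth probabilities for one sponge/medium.

    Growers are taxa of modest inoculum abundance (including any planted
    novel members) whose colony-mixture shares are set well above their
    inoculum abundance, so true growth satisfies the increase criterion;
    the dominant spike-in takes ``dominant_share`` of the colony mixture.
    """
    rng = np.random.default_rng(seed)
    novels = list(profile.novel_members)
    candidates = sorted(
        (t for t in profile.abundances if t not in novels),
        key=lambda t: profile.abundances[t],
    )
    grower_budget = 1.0 - scenario.dominant_share
    # Extra growers are admitted from the low-abundance end only while the
    # summed floor shares (twice each grower's inoculum abundance) fit in
    # the grower budget: a plate cannot support more detectable growers
    # than that, and every admitted grower's share can then exceed its
    # inoculum abundance (growth stays detectable by the increase rule).
    n_extra = max(0, scenario.n_growers - len(novels))
    budget_used = sum(2 * profile.abundances[t] for t in novels)
    extra: list[str] = []
    for t in candidates:  # ascending abundance
        if len(extra) >= n_extra:
            break
        need = 2 * profile.abundances[t]
        if budget_used + need <= 0.9 * grower_budget:
            extra.append(t)
            budget_used += need
    growers = novels + extra
    # target colony-mixture shares: equal-ish with mild variation, but at
    # least twice each grower's inoculum abundance (floor), so that true
    # growth always satisfies the increase criterion
    base = 1.0 + 0.4 * rng.random(len(growers))
    base = base / base.sum() * grower_budget
    floors = np.array([2.0 * profile.abundances[t] for t in growers])
    shares = np.maximum(base, floors)
    for _ in range(20):
        over = shares.sum() - grower_budget
        if over <= 1e-12:
            break
        slack = shares - floors
        free = slack > 0
        shares[free] -= over * slack[free] / slack[free].sum()
        shares = np.maximum(shares, floors)
    # growth_prob realising those shares through w = abundance * prob
    probs = {t: s / profile.abundances[t] for t, s in zip(growers, shares)}
    scale = max(probs.values())
    growth_prob = {t: p / scale for t, p in probs.items()}
    # spike weight giving the dominant its share after the same scaling
    grower_w = sum(profile.abundances[t] * growth_prob[t] for t in growers)
    spike_weight = scenario.dominant_share / (1.0 - scenario.dominant_share) * grower_w
    return PlatingScenario(
        growth_prob=growth_prob,
        dominance_factor=1.0,
        dominant_taxon="PSVLIKE",
        spike_in={"PSVLIKE": (dominant_template, spike_weight)},
        carryover_reads_fraction=scenario.carryover_reads_fraction,
        n_visible_colonies=n_visible_colonies,
    )


def run_simulation(scenario: SimulationScenario, seed: int,
                   outdir=None) -> SimulationResult:
    """Simulate the whole cultivation experiment: communities, plating,
    colony picking, barcoded reads and ground truth."""
    rng = np.random.default_rng(_subseed(seed, 11))
    refdb = generate_reference_db(scenario.n_reference_types, _subseed(seed, 13))

    # dominant fast grower: absent from inocula, ~96% identical to its
    # parent type strain, so it forms its own de novo OTU but is not novel
    dominant_parent = refdb.ids[-1]
    dominant_template = mutate_to_divergence(
        SequenceRecord(dominant_parent, refdb.v1v2(dominant_parent)),
        scenario.dominant_divergence, _subseed(seed, 17), new_id="PSVLIKE",
    ).bases

    truth = GroundTruth()
    profiles: dict[str, CommunityProfile] = {}
    plating: dict[str, PlatingScenario] = {}
    entries: list[ManifestEntry] = []

    n_scraped = len(scenario.sample_grid())
    barcodes = generate_barcodes(
        len(scenario.sponges) + n_scraped + scenario.antibiotic_groups, rng
    )
    rev_barcodes = generate_barcodes(scenario.colonies_per_plate, rng)
    bc = iter(barcodes)

    inoc_profiles: dict[str, CommunityProfile] = {}
    for si, sponge in enumerate(scenario.sponges):
        divs = scenario.novel_divergences
        novel_spec = [NovelSpec(d, abundance=scenario.novel_abundance) for d in divs]
        prof = simulate_community(
            refdb, scenario.n_taxa_per_sponge,
            lognormal_params=(0.0, scenario.lognormal_sigma),
            novel_spec=novel_spec, seed=_subseed(seed, 19, si),
            exclude={dominant_parent},
        )
        # give novel taxa sponge-specific names so they stay distinct
        renamed = {}
        for t in list(prof.abundances):
            new = f"{sponge}_{t}" if t.startswith("novel") else t
            renamed[t] = new
        prof = CommunityProfile(
            {renamed[t]: a for t, a in prof.abundances.items()},
            {renamed.get(t, t): s for t, s in prof.templates.items()},
            {renamed[t]: v for t, v in prof.novel_members.items()},
        )
        sid = f"{sponge}_inoc"
        inoc_profiles[sponge] = prof
        profiles[sid] = prof
        entries.append(ManifestEntry(
            sample_id=sid, fwd_barcode=next(bc), fwd_primer=FWD_PRIMER,
            rev_primer=REV_PRIMER, sponge=sponge, role="inoculum",
        ))

    # scraped plate communities
    for gi, (sponge, medium, surface, day) in enumerate(scenario.sample_grid()):
        prof = inoc_profiles[sponge]
        n_colonies = 20 + int(np.random.default_rng(_subseed(seed, 23, gi)).poisson(40))
        plate = design_plating_scenario(prof, scenario, refdb, dominant_template,
                                        _subseed(seed, 29, gi), n_colonies)
        scraped, ptruth = simulate_plating(prof, plate, _subseed(seed, 31, gi))
        sid = f"{sponge}_{medium}_{surface}_d{day}"
        profiles[sid] = scraped
        plating[sid] = plate
        truth.grown[sid] = sorted(ptruth.grown)
        truth.visible_colonies[sid] = n_colonies
        entries.append(ManifestEntry(
            sample_id=sid, fwd_barcode=next(bc), fwd_primer=FWD_PRIMER,
            rev_primer=REV_PRIMER, sponge=sponge, medium=medium, surface=surface,
            day=day, colonies=n_colonies, role="scraped",
        ))

    # antibiotic plates: colonies picked and double-barcoded
    for pi in range(scenario.antibiotic_groups):
        sponge = scenario.sponges[pi % len(scenario.sponges)]
        medium = scenario.media[pi % len(scenario.media)]
        prof = inoc_profiles[sponge]
        plate = design_plating_scenario(prof, scenario, refdb, dominant_template,
                                        _subseed(seed, 37, pi), 50)
        group = f"AB{pi + 1:02d}"
        fwd = next(bc)
        picks = simulate_colony_pick(prof, plate, scenario.colonies_per_plate,
                                     _subseed(seed, 41, pi),
                                     id_prefix=f"{group}_c")
        for ci, (cid, taxon) in enumerate(picks):
            truth.colony_taxon[cid] = taxon
            tpl = (dominant_template if taxon == "PSVLIKE"
                   else prof.templates[taxon])
            profiles[cid] = CommunityProfile({taxon: 1.0}, {taxon: tpl},
                                             {k: v for k, v in prof.novel_members.items()
                                              if k == taxon})
            entries.append(ManifestEntry(
                sample_id=cid, fwd_barcode=fwd, rev_barcode=rev_barcodes[ci],
                fwd_primer=FWD_PRIMER, rev_primer=REV_PRIMER, sponge=sponge,
                medium=medium, surface="agar", role="colony", plate_group=group,
            ))

    manifest = SampleManifest(entries)
    n_reads = {e.sample_id: (scenario.reads_per_colony if e.role == "colony"
                             else scenario.reads_per_sample)
               for e in entries}
    reads, truth = simulate_reads(profiles, manifest, scenario.error_model,
                                  n_reads, seed=_subseed(seed, 43), truth=truth)
    result = SimulationResult(refdb, manifest, reads, truth, profiles,
                              plating, scenario)
    if outdir is not None:
        result.write(outdir)
    return result
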