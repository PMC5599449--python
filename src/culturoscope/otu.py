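"""Open-reference greedy OTU picking at 97% identity.

Stage 1 (closed reference): each read is assigned to the best reference
whose V1-V2 window it matches at or above the identity threshold.
Stage 2 (de novo): the remaining reads, sorted by descending duplicate
count, then descending length, then lexicographic id, are clustered
greedily — a read joins the first existing centroid it matches at or
above the threshold, otherwise it founds a new OTU and becomes its
centroid.  Centroids are not recomputed as members join (single-pass
greedy), so the representative of every OTU is the sequence that was
actually used for picking.

A simplified two-parent chimera (bimera) screen is available but ships
disabled: it flags an OTU when some single-crossover combination of two
parent sequences explains the representative substantially better than
any single parent does.  It is a deliberately simple stand-in for
dedicated chimera detectors and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seq import AlignScoring, SequenceRecord, global_align, percent_identity
from .simulate import ReferenceDb

__all__ = [
    "Otu",
    "OtuTable",
    "BimeraParams",
    "pick_otus_open_reference",
    "assign_taxonomy",
    "flag_bimeras",
    "build_otu_table",
]

DEFAULT_THRESHOLD = 97.0

# identity bands for taxonomy truncation: (min identity, lineage ranks kept)
DEFAULT_TAX_BANDS = ((97.0, 6), (95.0, 5), (90.0, 4), (85.0, 3), (80.0, 2))


@dataclass
class Otu:
    """A 97%-identity cluster with its centroid representative."""

    otu_id: str
    representative: SequenceRecord
    members: list[str]
    taxonomy: str = "Unassigned"
    origin: str = "denovo"  # "closed" | "denovo"
    chimera_flag: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"OTU {self.otu_id} has no members")

    @property
    def size(self) -> int:
        return len(self.members)


class _IdentityCache:
    """Memoised percent identity between sequence strings."""

    def __init__(self, scoring: AlignScoring):
        self.scoring = scoring
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        val = self._cache.get(key)
        if val is None:
            val = percent_identity(a, b, self.scoring)
            self._cache[key] = val
        return val


def pick_otus_open_reference(
    reads: list[SequenceRecord],
    refdb: ReferenceDb,
    threshold: float = DEFAULT_THRESHOLD,
    scoring: AlignScoring = AlignScoring(),
) -> list[Otu]:
    """Two-stage open-reference clustering; deterministic given inputs.

    Returns closed-reference OTUs (id = reference id, representative =
    reference V1-V2 window) followed by de novo OTUs (``denovo1``, ... in
    creation order, representative = founding read).
    """
    if not reads:
        return []
    identity = _IdentityCache(scoring)

    # duplicate groups, keyed by exact sequence
    groups: dict[str, list[str]] = {}
    for r in reads:
        groups.setdefault(r.bases, []).append(r.id)

    ref_windows = [(rid, refdb.v1v2(rid)) for rid in refdb.ids]

    closed_members: dict[str, list[str]] = {}
    leftovers: list[str] = []
    for seq, ids in groups.items():
        best_ref, best_pid = None, -1.0
        for rid, win in ref_windows:
            pid = identity(seq, win)
            if pid > best_pid or (pid == best_pid and best_ref is not None and rid < best_ref):
                best_ref, best_pid = rid, pid
        if best_pid >= threshold:
            closed_members.setdefault(best_ref, []).extend(ids)
        else:
            leftovers.append(seq)

    # de novo: abundance-sorted greedy centroid clustering
    leftovers.sort(key=lambda s: (-len(groups[s]), -len(s), min(groups[s])))
    centroids: list[str] = []
    denovo_members: list[list[str]] = []
    for seq in leftovers:
        placed = False
        for ci, cen in enumerate(centroids):
            if identity(seq, cen) >= threshold:
                denovo_members[ci].extend(groups[seq])
                placed = True
                break
        if not placed:
            centroids.append(seq)
            denovo_members.append(list(groups[seq]))

    otus: list[Otu] = []
    for rid in sorted(closed_members):
        win = refdb.v1v2(rid)
        otus.append(Otu(rid, SequenceRecord(rid, win), sorted(closed_members[rid]),
                        origin="closed"))
    for i, (cen, members) in enumerate(zip(centroids, denovo_members), start=1):
        rep_id = f"denovo{i}"
        otus.append(Otu(rep_id, SequenceRecord(rep_id, cen), sorted(members),
                        origin="denovo"))
    return otus


def assign_taxonomy(
    otu: Otu,
    refdb: ReferenceDb,
    bands: tuple[tuple[float, int], ...] = DEFAULT_TAX_BANDS,
    scoring: AlignScoring = AlignScoring(),
) -> str:
    """Transfer the lineage of the best reference hit, truncated by identity.

    Closed OTUs inherit the full reference lineage.  De novo OTUs take
    the best hit's lineage cut to the number of ranks the identity band
    supports; below the lowest band the OTU is "Unassigned".
    """
    if otu.origin == "closed":
        return refdb.taxonomy[otu.otu_id]
    best_ref, best_pid = None, -1.0
    for rid in refdb.ids:
        pid = percent_identity(otu.representative.bases, refdb.v1v2(rid), scoring)
        if pid > best_pid or (pid == best_pid and best_ref is not None and rid < best_ref):
            best_ref, best_pid = rid, pid
    for min_ident, n_ranks in bands:
        if best_pid >= min_ident:
            ranks = refdb.taxonomy[best_ref].split("; ")
            return "; ".join(ranks[:n_ranks])
    return "Unassigned"


@dataclass(frozen=True)
class BimeraParams:
    """Thresholds for the simplified two-parent chimera screen."""

    segment_identity: float = 90.0  # each half must match its parent this well
    margin: float = 5.0             # crossover must beat best single parent by this


def _match_profile(rep: str, parent: str, scoring: AlignScoring) -> list[int]:
    """Per-position match indicator of ``rep`` against ``parent``,
    projected onto rep coordinates."""
    from .seq import _bases_match  # column-level match rule shared with identity

    aln = global_align(rep, parent, scoring)
    out = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-":
            out.append(1 if _bases_match(x, y) else 0)
    return out


def flag_bimeras(
    otus: list[Otu],
    refdb: ReferenceDb | None = None,
    params: BimeraParams = BimeraParams(),
    scoring: AlignScoring = AlignScoring(),
) -> list[Otu]:
    """Set ``chimera_flag`` on OTUs explainable as a single crossover of
    two parents (other OTU representatives plus the reference windows).

    The flag set is invariant to the order of parents.  Mutates and
    returns ``otus``.
    """
    parents: dict[str, str] = {}
    for o in otus:
        parents[o.otu_id] = o.representative.bases
    if refdb is not None:
        for rid in refdb.ids:
            parents.setdefault(rid, refdb.v1v2(rid))
    if len(parents) < 2:
        return otus

    for otu in otus:
        rep = otu.representative.bases
        L = len(rep)
        cands = {pid: seq for pid, seq in parents.items()
                 if pid != otu.otu_id and seq != rep}
        if len(cands) < 2:
            otu.chimera_flag = False
            continue
        profiles = {}
        prefix = {}
        best_single = 0.0
        for pid in sorted(cands):
            prof = _match_profile(rep, cands[pid], scoring)
            profiles[pid] = prof
            pre = [0]
            for v in prof:
                pre.append(pre[-1] + v)
            prefix[pid] = pre
            best_single = max(best_single, 100.0 * pre[-1] / L)
        flagged = False
        ids = sorted(cands)
        for p in ids:
            for q in ids:
                if p == q:
                    continue
                pre_p, pre_q = prefix[p], prefix[q]
                for k in range(1, L):
                    left = 100.0 * pre_p[k] / k
                    right = 100.0 * (pre_q[L] - pre_q[k]) / (L - k)
                    combined = 100.0 * (pre_p[k] + pre_q[L] - pre_q[k]) / L
                    if (left >= params.segment_identity
                            and right >= params.segment_identity
                            and combined - best_single >= params.margin):
                        flagged = True
                        break
                if flagged:
                    break
            if flagged:
                break
        otu.chimera_flag = flagged
    return otus


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with per-sample metadata."""

    counts: pd.DataFrame                    # index: sample ids, columns: otu ids
    otus: dict[str, Otu] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None    # indexed by sample id

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("OTU table has negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    def to_biom_json(self, path) -> None:
        """Minimal BIOM-format-compatible (v1, dense) JSON export."""
        import json

        data = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [len(self.counts.columns), len(self.counts.index)],
            "rows": [{"id": o, "metadata": {"taxonomy": self.otus[o].taxonomy}
                      if o in self.otus else None}
                     for o in self.counts.columns],
            "columns": [{"id": s, "metadata": None} for s in self.counts.index],
            "data": self.counts.T.values.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(data, fh)


def build_otu_table(
    otus: list[Otu],
    read_to_sample: dict[str, str],
    drop_flagged: bool = True,
    sample_order: list[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> OtuTable:
    """Tally member reads per sample into a count matrix.

    Chimera-flagged OTUs are excluded when ``drop_flagged``; all-zero
    columns never appear.  Raises ``KeyError`` for a member read with no
    sample mapping.
    """
    kept = [o for o in otus if not (drop_flagged and o.chimera_flag)]
    samples = sample_order or sorted({read_to_sample[r] for o in kept for r in o.members})
    counts = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                          columns=[o.otu_id for o in kept], dtype=int)
    for o in kept:
        for rid in o.members:
            try:
                sample = read_to_sample[rid]
            except KeyError:
                raise KeyError(f"read {rid!r} (OTU {o.otu_id}) has no sample mapping")
            if sample in counts.index:
                counts.loc[sample, o.otu_id] += 1
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    otu_map = {o.otu_id: o for o in kept if o.otu_id in counts.columns}
    return OtuTable(counts, otu_map, metadata)
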