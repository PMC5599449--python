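"""Colony identification by read majority, and isolate confirmation.

A picked colony yields a handful of double-barcoded reads; many carry
stray OTUs from carry-over template or sequencing artefacts.  A colony
is identified with an OTU only when that OTU accounts for a strict
majority (> 50%) of the reads obtained for the colony — a 50/50 split
leaves the colony unassigned.  Isolates regrown from glycerol stocks
are confirmed by Sanger sequence identity > 97% to the representative
read of the target OTU.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .seq import AlignScoring, SequenceRecord, percent_identity
from .otu import Otu

__all__ = [
    "ColonyAssignment",
    "IsolateConfirmation",
    "assign_colony",
    "select_otus_for_regrowth",
    "confirm_isolate",
    "assignments_frame",
]


@dataclass
class ColonyAssignment:
    """Per-colony OTU read counts and the strict-majority decision."""

    colony_id: str
    total_reads: int
    otu_read_counts: dict[str, int]
    assigned_otu: str | None = field(init=False)
    majority_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        labelled = sum(self.otu_read_counts.values())
        if labelled > self.total_reads:
            raise ValueError(
                f"colony {self.colony_id}: {labelled} labelled reads exceed "
                f"total {self.total_reads}"
            )
        if self.total_reads == 0 or not self.otu_read_counts:
            self.assigned_otu = None
            self.majority_fraction = 0.0
            return
        # modal OTU; ties broken lexicographically (a tie can never win anyway)
        top = min(self.otu_read_counts, key=lambda o: (-self.otu_read_counts[o], o))
        frac = self.otu_read_counts[top] / self.total_reads
        self.majority_fraction = frac
        self.assigned_otu = top if frac > 0.5 else None


def assign_colony(
    colony_id: str,
    read_otu_labels: dict[str, str | None] | list[str | None],
    include_unlabeled: bool = True,
) -> ColonyAssignment:
    """Assign the modal OTU iff it exceeds 50% of the colony's reads.

    ``read_otu_labels`` maps read id to OTU id (``None`` for reads that
    clustered nowhere).  Unlabelled reads count in the denominator by
    default (conservative); set ``include_unlabeled=False`` to compute
    the majority over labelled reads only.  A colony with zero retained
    reads is recorded as unassigned, not an error.
    """
    labels = list(read_otu_labels.values()) if isinstance(read_otu_labels, dict) \
        else list(read_otu_labels)
    counts = Counter(l for l in labels if l is not None)
    total = len(labels) if include_unlabeled else sum(counts.values())
    return ColonyAssignment(colony_id, total, dict(counts))


def select_otus_for_regrowth(assignments: list[ColonyAssignment]) -> set[str]:
    """OTUs assigned (strict majority) to at least one colony."""
    return {a.assigned_otu for a in assignments if a.assigned_otu is not None}


@dataclass
class IsolateConfirmation:
    """Sanger-vs-representative identity check for a regrown isolate."""

    isolate_id: str
    target_otu: str
    sanger_identity: float
    confirmed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.confirmed = self.sanger_identity > 97.0


def confirm_isolate(
    sanger: SequenceRecord,
    otu: Otu,
    scoring: AlignScoring = AlignScoring(),
) -> IsolateConfirmation:
    """Confirm an isolate iff its Sanger read is > 97% identical to the
    OTU representative over their overlapping region (free end gaps make
    the comparison insensitive to the Sanger read extending past the
    amplicon)."""
    ident = percent_identity(sanger, otu.representative, scoring)
    return IsolateConfirmation(sanger.id, otu.otu_id, ident)


def assignments_frame(assignments: list[ColonyAssignment]) -> pd.DataFrame:
    """Tabular colony-assignment summary (one row per colony)."""
    rows = []
    for a in assignments:
        top = max(a.otu_read_counts, key=a.otu_read_counts.get) if a.otu_read_counts else ""
        rows.append({
            "colony_id": a.colony_id,
            "n_reads": a.total_reads,
            "top_otu": top,
            "fraction": round(a.majority_fraction, 4),
            "assigned": a.assigned_otu or "",
        })
    return pd.DataFrame(rows)
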