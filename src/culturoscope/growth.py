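"""Growth detection, taxonomic novelty and OTU-set overlap analysis.

Plate scraping has a caveat: cell material carried over from the
inoculum is sequenced alongside colonies, so taxa can be detected that
never grew.  Three conservative criteria decide growth of an OTU in a
scraped community:

I.   its relative abundance increased compared to the inoculum
     (strictly; an OTU absent from the inoculum trivially increased),
II.  its relative abundance is >= 0.2%, and
III. the scraped community comprised >= 20 visible colonies.

Novelty is classified against a type-strain database: an OTU is novel
when its representative is <= 95% identical to the closest type strain,
and order-level novel below 89%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .seq import AlignScoring, percent_identity
from .otu import Otu, OtuTable
from .simulate import ReferenceDb

__all__ = [
    "GrowthParams",
    "GrowthCall",
    "NoveltyCall",
    "relative_abundances",
    "call_growth",
    "classify_novelty",
    "overlap_sets",
    "summarize_novel_growth",
    "growth_calls_frame",
    "novelty_frame",
]


@dataclass(frozen=True)
class GrowthParams:
    """Thresholds of the three growth criteria."""

    min_rel_abundance: float = 0.002   # criterion II, inclusive
    min_visible_colonies: int = 20     # criterion III, inclusive
    require_increase: bool = True      # criterion I

    def __post_init__(self) -> None:
        if self.min_rel_abundance < 0 or self.min_visible_colonies < 0:
            raise ValueError("growth thresholds must be non-negative")


@dataclass
class GrowthCall:
    """Per-OTU growth decision in one scraped sample, with criterion flags."""

    otu: str
    sample: str
    rel_abundance_scraped: float
    rel_abundance_inoculum: float
    visible_colonies: int
    c1_increase: bool = field(init=False)
    c2_abundance: bool = field(init=False)
    c3_colonies: bool = field(init=False)
    grew: bool = field(init=False)

    params: GrowthParams = field(default_factory=GrowthParams)

    def __post_init__(self) -> None:
        p = self.params
        self.c1_increase = (not p.require_increase) or (
            self.rel_abundance_scraped > self.rel_abundance_inoculum
        )
        self.c2_abundance = self.rel_abundance_scraped >= p.min_rel_abundance
        self.c3_colonies = self.visible_colonies >= p.min_visible_colonies
        self.grew = self.c1_increase and self.c2_abundance and self.c3_colonies


@dataclass
class NoveltyCall:
    """Identity of an OTU to its closest type strain, with novelty flags."""

    otu: str
    closest_type_strain: str
    identity: float
    is_novel: bool = field(init=False)
    order_level_novel: bool = field(init=False)

    novelty_threshold: float = 95.0       # inclusive
    order_threshold: float = 89.0         # exclusive

    def __post_init__(self) -> None:
        self.is_novel = self.identity <= self.novelty_threshold
        self.order_level_novel = self.identity < self.order_threshold


def relative_abundances(table: OtuTable) -> pd.DataFrame:
    """Row-normalise the count matrix; zero-count samples are dropped
    with a warning."""
    sums = table.counts.sum(axis=1)
    empty = sums[sums == 0].index.tolist()
    if empty:
        warnings.warn(f"excluding zero-count samples: {empty}")
    kept = table.counts.loc[sums > 0]
    return kept.div(kept.sum(axis=1), axis=0)


def call_growth(
    table: OtuTable,
    scraped_sample: str,
    inoculum_sample: str,
    params: GrowthParams = GrowthParams(),
    visible_colonies: int | None = None,
) -> list[GrowthCall]:
    """Apply the three growth criteria to every OTU detected in a scraped
    sample, against its inoculum.

    The visible-colony count is read from the table metadata (``colonies``
    column) unless given explicitly; a missing count is an error naming
    the sample.
    """
    rel = relative_abundances(table)
    for s in (scraped_sample, inoculum_sample):
        if s not in rel.index:
            raise KeyError(f"sample {s!r} not in the relative-abundance table")
    if visible_colonies is None:
        meta = table.metadata
        if meta is None or "colonies" not in meta.columns or \
                scraped_sample not in meta.index or pd.isna(meta.loc[scraped_sample, "colonies"]):
            raise ValueError(f"no visible-colony count for sample {scraped_sample!r}")
        visible_colonies = int(meta.loc[scraped_sample, "colonies"])
    calls = []
    for otu_id in rel.columns:
        scraped = float(rel.loc[scraped_sample, otu_id])
        if scraped == 0:
            continue  # OTUs absent from the scraped sample are not called
        inoc = float(rel.loc[inoculum_sample, otu_id])
        calls.append(GrowthCall(otu_id, scraped_sample, scraped, inoc,
                                visible_colonies, params=params))
    return calls


def classify_novelty(
    otu: Otu,
    type_strain_db: ReferenceDb,
    novelty_threshold: float = 95.0,
    order_threshold: float = 89.0,
    scoring: AlignScoring = AlignScoring(),
) -> NoveltyCall:
    """Best identity of the representative over all type strains
    (V1-V2 windows), with the <=95% novelty and <89% order-level rules."""
    if len(type_strain_db) == 0:
        raise ValueError("empty type-strain database")
    best_id, best_pid = None, -1.0
    for rid in type_strain_db.ids:
        pid = percent_identity(otu.representative.bases, type_strain_db.v1v2(rid), scoring)
        if pid > best_pid or (pid == best_pid and best_id is not None and rid < best_id):
            best_id, best_pid = rid, pid
    call = NoveltyCall(otu.otu_id, best_id, best_pid,
                       novelty_threshold=novelty_threshold,
                       order_threshold=order_threshold)
    return call


def overlap_sets(
    detection: dict[str, set[str]] | None = None,
    table: OtuTable | None = None,
    groupings: dict[str, list[str]] | None = None,
    presence_min: int = 1,
) -> dict[tuple[str, ...], int]:
    """Venn region counts over k groups of pooled samples.

    Either pass ``detection`` (group -> set of OTU ids) directly, or a
    table plus ``groupings`` (group -> sample ids); an OTU is detected
    in a group when its pooled count is >= ``presence_min``.  Returns
    counts for all 2^k - 1 regions, keyed by the sorted tuple of groups
    whose exclusive intersection the region is.
    """
    if detection is None:
        if table is None or groupings is None:
            raise ValueError("need either detection sets or a table with groupings")
        detection = {}
        for group, samples in groupings.items():
            pooled = table.counts.loc[[s for s in samples if s in table.counts.index]].sum(axis=0)
            detection[group] = set(pooled[pooled >= presence_min].index)
    groups = sorted(detection)
    if len(groups) > 5:
        raise ValueError("overlap analysis limited to 5 groups for readability")
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(groups) + 1):
        for combo in combinations(groups, k):
            inside = set.intersection(*(detection[g] for g in combo))
            outside = set.union(*(detection[g] for g in groups if g not in combo)) \
                if len(combo) < len(groups) else set()
            regions[combo] = len(inside - outside)
    return regions


def summarize_novel_growth(
    growth_calls: list[GrowthCall],
    novelty_calls: dict[str, NoveltyCall] | list[NoveltyCall],
    metadata: pd.DataFrame | None = None,
    min_rel_for_report: float = 0.0,
) -> pd.DataFrame:
    """Report of novel OTUs meeting the growth criteria in >= 1 sample.

    One row per novel grown OTU: closest type strain, identity, number
    of qualifying samples, the maximum relative abundance over them, and
    the source sponges and media (from sample metadata when available).
    """
    if isinstance(novelty_calls, list):
        novelty_calls = {c.otu: c for c in novelty_calls}
    qualifying: dict[str, list[GrowthCall]] = {}
    for call in growth_calls:
        nov = novelty_calls.get(call.otu)
        if nov is None or not nov.is_novel:
            continue
        if call.grew and call.rel_abundance_scraped >= min_rel_for_report:
            qualifying.setdefault(call.otu, []).append(call)
    rows = []
    for otu_id in sorted(qualifying):
        calls = qualifying[otu_id]
        nov = novelty_calls[otu_id]
        sponges, media = set(), set()
        if metadata is not None:
            for c in calls:
                if c.sample in metadata.index:
                    sponges.add(str(metadata.loc[c.sample].get("sponge", "")))
                    media.add(str(metadata.loc[c.sample].get("medium", "")))
        rows.append({
            "otu_id": otu_id,
            "closest_type_strain": nov.closest_type_strain,
            "identity_pct": round(nov.identity, 2),
            "n_samples": len(calls),
            "max_rel_abundance_pct": round(
                100 * max(c.rel_abundance_scraped for c in calls), 3),
            "sponges": ",".join(sorted(s for s in sponges if s)),
            "media": ",".join(sorted(m for m in media if m)),
        })
    df = pd.DataFrame(rows, columns=[
        "otu_id", "closest_type_strain", "identity_pct", "n_samples",
        "max_rel_abundance_pct", "sponges", "media",
    ])
    return df.sort_values("identity_pct").reset_index(drop=True) if len(df) else df


def growth_calls_frame(calls: list[GrowthCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "otu_id": c.otu, "sample": c.sample,
        "rel_abundance_scraped": c.rel_abundance_scraped,
        "rel_abundance_inoculum": c.rel_abundance_inoculum,
        "visible_colonies": c.visible_colonies,
        "c1_increase": c.c1_increase, "c2_abundance": c.c2_abundance,
        "c3_colonies": c.c3_colonies, "grew": c.grew,
    } for c in calls])


def novelty_frame(calls: list[NoveltyCall] | dict[str, NoveltyCall]) -> pd.DataFrame:
    if isinstance(calls, dict):
        calls = list(calls.values())
    return pd.DataFrame([{
        "otu_id": c.otu, "closest_type_strain": c.closest_type_strain,
        "identity_pct": round(c.identity, 2),
        "is_novel": c.is_novel, "order_level_novel": c.order_level_novel,
    } for c in calls])
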