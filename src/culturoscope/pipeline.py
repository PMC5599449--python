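"""End-to-end orchestration: simulate -> demux -> cluster -> colonies /
growth -> stats, as one reproducible, seeded run.

Every threshold the analysis applies (mean quality > 25, homopolymer
<= 6, length >= 200, 0 primer mismatches, 97% clustering identity,
> 50% colony majority, growth criteria 0.2% / 20 colonies, novelty
<= 95% / < 89%, Sanger confirmation > 97%) is a named config key, echoed
into the run directory together with a per-stage accounting log, so any
run can be audited and reproduced from its output directory alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demux as dx
from . import simulate as sim
from .colony import assign_colony, assignments_frame, select_otus_for_regrowth
from .growth import (GrowthParams, call_growth, classify_novelty,
                     growth_calls_frame, novelty_frame, overlap_sets,
                     relative_abundances, summarize_novel_growth)
from .otu import (BimeraParams, assign_taxonomy, build_otu_table,
                  flag_bimeras, pick_otus_open_reference)
from .seq import SequenceRecord, percent_identity, read_fasta, write_fasta
from .stats import distance_matrix, hclust_upgma, rarefaction_curve, shannon, simper

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_against_truth"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    seed: int = 1
    # input mode: "simulate" generates data; "files" reads the paths below
    mode: str = "simulate"
    scenario: str = "demo"                  # "demo" | "study"
    scenario_overrides: dict = field(default_factory=dict)
    reads_path: str | None = None
    manifest_path: str | None = None
    reference_fasta: str | None = None
    reference_taxonomy: str | None = None
    # filtering
    min_mean_quality: float = 25.0
    max_homopolymer: int = 6
    min_length: int = 200
    max_primer_mismatches: int = 0
    # clustering
    otu_threshold: float = 97.0
    chimera_check: bool = False
    # growth + novelty
    min_rel_abundance: float = 0.002
    min_visible_colonies: int = 20
    novelty_threshold: float = 95.0
    order_threshold: float = 89.0
    sanger_confirm_threshold: float = 97.0
    # stats
    shannon_base: float | None = None
    simper_sqrt: bool = True
    rarefaction_reps: int = 10

    def filter_params(self) -> dx.FilterParams:
        return dx.FilterParams(self.min_mean_quality, self.max_homopolymer,
                               self.min_length, self.max_primer_mismatches)

    def growth_params(self) -> GrowthParams:
        return GrowthParams(self.min_rel_abundance, self.min_visible_colonies)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _scenario(config: RunConfig) -> sim.SimulationScenario:
    builder = {"demo": sim.demo_scenario, "study": sim.study_scenario}
    if config.scenario not in builder:
        raise PipelineError(f"simulate: unknown scenario {config.scenario!r}")
    overrides = dict(config.scenario_overrides)
    if "error_model" in overrides and isinstance(overrides["error_model"], dict):
        overrides["error_model"] = sim.ErrorModel(**overrides["error_model"])
    return builder[config.scenario](**overrides)


@dataclass
class RunResult:
    """Handles to the main in-memory products of a pipeline run."""

    outdir: Path
    table: object
    otus: list
    report: dx.FilterReport
    growth_calls: list
    novelty: dict
    colony_assignments: list


def run_pipeline(config: RunConfig, outdir) -> RunResult:
    """Execute the full pipeline into ``outdir``; deterministic given the
    config seed (all emitted files are byte-reproducible)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(stage: str, msg: str) -> None:
        log.append(f"[{stage}] {msg}")

    config.to_yaml(outdir / "config.yaml")

    # --- stage: inputs -----------------------------------------------------
    try:
        if config.mode == "simulate":
            scenario = _scenario(config)
            result = sim.run_simulation(scenario, config.seed, outdir=outdir / "inputs")
            reads, manifest, refdb = result.reads, result.manifest, result.refdb
            truth = result.truth
            note("simulate", f"scenario={config.scenario} seed={config.seed} "
                             f"reads={len(reads)} samples={len(manifest)}")
        elif config.mode == "files":
            from .seq import read_fastq

            reads = read_fastq(config.reads_path)
            manifest = dx.SampleManifest.from_tsv(config.manifest_path)
            refdb = sim.ReferenceDb.read(config.reference_fasta, config.reference_taxonomy)
            truth = None
            note("input", f"reads={len(reads)} samples={len(manifest)}")
        else:
            raise PipelineError(f"inputs: unknown mode {config.mode!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"inputs: {exc}") from exc

    # --- stage: demux + filter --------------------------------------------
    try:
        params = config.filter_params()
        clean, report = dx.filter_library(reads, manifest, params)
        report.to_tsv(outdir / "filter_report.tsv")
        note("demux", f"thresholds: mean_quality>{params.min_mean_quality} "
                      f"homopolymer<={params.max_homopolymer} "
                      f"length>={params.min_length} "
                      f"primer_mismatches<={params.max_primer_mismatches}")
        note("demux", f"retained {report.n_retained}/{report.n_input} reads")
    except Exception as exc:
        raise PipelineError(f"demux: {exc}") from exc

    # --- stage: clustering -------------------------------------------------
    try:
        all_clean = [r for target in sorted(clean) for r in clean[target]]
        # retained reads are unique by id; map back to their bin
        read_to_sample = {r.id: target for target in clean for r in clean[target]}
        otus = pick_otus_open_reference(all_clean, refdb, config.otu_threshold)
        for o in otus:
            o.taxonomy = assign_taxonomy(o, refdb)
        if config.chimera_check:
            flag_bimeras(otus, refdb, BimeraParams())
        note("cluster", f"threshold={config.otu_threshold} "
                        f"otus={len(otus)} "
                        f"(closed={sum(o.origin == 'closed' for o in otus)}, "
                        f"denovo={sum(o.origin == 'denovo' for o in otus)}) "
                        f"chimera_check={config.chimera_check}")
        metadata = manifest.metadata_frame()
        table = build_otu_table(otus, read_to_sample,
                                drop_flagged=config.chimera_check,
                                metadata=metadata)
        table.to_tsv(outdir / "otu_table.tsv")
        write_fasta([o.representative for o in otus], outdir / "representatives.fasta")
        pd.DataFrame([{"otu_id": o.otu_id, "origin": o.origin, "size": o.size,
                       "taxonomy": o.taxonomy, "chimera_flag": o.chimera_flag}
                      for o in otus]).to_csv(outdir / "otus.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"cluster: {exc}") from exc

    # --- stage: colonies ---------------------------------------------------
    colony_assignments = []
    try:
        read_to_otu = {rid: o.otu_id for o in otus for rid in o.members}
        colony_ids = [e.sample_id for e in manifest if e.role == "colony"]
        for cid in colony_ids:
            labels = [read_to_otu.get(r.id) for r in clean.get(cid, [])]
            colony_assignments.append(assign_colony(cid, labels))
        if colony_assignments:
            assignments_frame(colony_assignments).to_csv(
                outdir / "colony_assignments.tsv", sep="\t", index=False)
            regrow = select_otus_for_regrowth(colony_assignments)
            note("colonies", f"majority rule >50%: assigned "
                             f"{sum(a.assigned_otu is not None for a in colony_assignments)}"
                             f"/{len(colony_assignments)} colonies; "
                             f"{len(regrow)} OTUs selected for regrowth")
    except Exception as exc:
        raise PipelineError(f"colonies: {exc}") from exc

    # --- stage: growth + novelty -------------------------------------------
    try:
        gparams = config.growth_params()
        inoc_by_sponge = {e.sponge: e.sample_id for e in manifest if e.role == "inoculum"}
        growth_calls = []
        for e in manifest:
            if e.role != "scraped" or e.sample_id not in table.counts.index:
                continue
            inoc = inoc_by_sponge.get(e.sponge)
            if inoc is None or inoc not in table.counts.index:
                continue
            growth_calls.extend(call_growth(table, e.sample_id, inoc, gparams))
        growth_calls_frame(growth_calls).to_csv(outdir / "growth_calls.tsv",
                                                sep="\t", index=False)
        novelty = {o.otu_id: classify_novelty(o, refdb, config.novelty_threshold,
                                              config.order_threshold)
                   for o in otus}
        novelty_frame(novelty).to_csv(outdir / "novelty.tsv", sep="\t", index=False)
        table1 = summarize_novel_growth(growth_calls, novelty, metadata)
        table1.to_csv(outdir / "novel_growth_report.tsv", sep="\t", index=False)
        note("growth", f"criteria: increase & rel_abundance>={gparams.min_rel_abundance} "
                       f"& colonies>={gparams.min_visible_colonies}; "
                       f"novelty<={config.novelty_threshold} order<{config.order_threshold}; "
                       f"{sum(c.grew for c in growth_calls)} grew calls, "
                       f"{len(table1)} novel cultivable OTUs")

        # OTU-set overlap: inoculum vs scraped vs picked colonies
        groupings: dict[str, list[str]] = {"sponge_samples": [], "scraped": [], "picked": []}
        for e in manifest:
            if e.role == "inoculum":
                groupings["sponge_samples"].append(e.sample_id)
            elif e.role == "scraped":
                groupings["scraped"].append(e.sample_id)
            elif e.role == "colony":
                groupings["picked"].append(e.sample_id)
        groupings = {g: s for g, s in groupings.items() if s}
        venn = overlap_sets(table=table, groupings=groupings)
        with open(outdir / "venn.tsv", "w") as fh:
            fh.write("region\tn_otus\n")
            for region, count in sorted(venn.items()):
                fh.write("&".join(region) + f"\t{count}\n")
    except Exception as exc:
        raise PipelineError(f"growth: {exc}") from exc

    # --- stage: stats ------------------------------------------------------
    try:
        rel = relative_abundances(table)
        shannon_rows = []
        for e in manifest:
            if e.role == "inoculum" and e.sample_id in table.counts.index:
                counts = table.counts.loc[e.sample_id].values
                shannon_rows.append({
                    "sample_id": e.sample_id,
                    "shannon": round(shannon(counts, config.shannon_base), 4),
                })
                rc = rarefaction_curve(
                    counts,
                    depths=sorted({max(1, int(counts.sum()) // d) for d in (10, 4, 2, 1)}),
                    n_reps=config.rarefaction_reps, seed=config.seed)
                rc.insert(0, "sample_id", e.sample_id)
                mode = "a" if (outdir / "rarefaction.tsv").exists() else "w"
                rc.to_csv(outdir / "rarefaction.tsv", sep="\t", index=False,
                          mode=mode, header=(mode == "w"))
        pd.DataFrame(shannon_rows).to_csv(outdir / "shannon.tsv", sep="\t", index=False)

        community_samples = [e.sample_id for e in manifest
                             if e.role in ("inoculum", "scraped")
                             and e.sample_id in rel.index]
        dm = None
        if len(community_samples) >= 2:
            dm = distance_matrix(rel.loc[community_samples])
            dm.to_tsv(outdir / "bray_curtis.tsv")
            dendro = hclust_upgma(dm)
            (outdir / "dendrogram.newick").write_text(dendro.to_newick() + "\n")

        sponges = sorted({e.sponge for e in manifest if e.role == "scraped" and e.sponge})
        simper_result = None
        if len(sponges) >= 2:
            ga = [e.sample_id for e in manifest
                  if e.role == "scraped" and e.sponge == sponges[0] and e.sample_id in rel.index]
            gb = [e.sample_id for e in manifest
                  if e.role == "scraped" and e.sponge == sponges[1] and e.sample_id in rel.index]
            if ga and gb:
                simper_result = simper(rel, ga, gb, sqrt_transform=config.simper_sqrt)
                simper_result.to_tsv(outdir / "simper.tsv")
                note("stats", f"SIMPER {sponges[0]} vs {sponges[1]}: overall "
                              f"dissimilarity {simper_result.overall_dissimilarity:.4f}")
    except Exception as exc:
        raise PipelineError(f"stats: {exc}") from exc

    # --- report ------------------------------------------------------------
    lines = ["# Pipeline run report", ""]
    lines += [f"- {l}" for l in log]
    lines += ["", "## Per-sample read retention", ""]
    retained = report.retained_counts()
    for target in sorted(retained.index):
        lines.append(f"- {target}: {retained[target]}")
    if colony_assignments:
        lines += ["", "## Colony assignments", "",
                  assignments_frame(colony_assignments).to_string(index=False)]
    if growth_calls:
        grew = [c for c in growth_calls if c.grew]
        lines += ["", f"## Growth calls: {len(grew)} of {len(growth_calls)} OTU-sample "
                      f"pairs meet all three criteria"]
    if shannon_rows:
        lines += ["", "## Shannon diversity (inocula)", ""]
        lines += [f"- {r['sample_id']}: H' = {r['shannon']}" for r in shannon_rows]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    (outdir / "run.log").write_text("\n".join(log) + "\n")

    return RunResult(outdir, table, otus, report, growth_calls, novelty,
                     colony_assignments)


# ---------------------------------------------------------------------------
# Validation against simulation ground truth
# ---------------------------------------------------------------------------


def _map_otus_to_taxa(representatives: list[SequenceRecord],
                      templates: dict[str, str],
                      threshold: float = 97.0) -> dict[str, str | None]:
    """Match each OTU representative to the true taxon template it came
    from (>= threshold identity), or None."""
    out: dict[str, str | None] = {}
    for rep in representatives:
        best_t, best_pid = None, -1.0
        for taxon in sorted(templates):
            pid = percent_identity(rep.bases, templates[taxon])
            if pid > best_pid:
                best_t, best_pid = taxon, pid
        out[rep.id] = best_t if best_pid >= threshold else None
    return out


def validate_against_truth(run_dir, ground_truth) -> pd.DataFrame:
    """Score a simulation-mode run against its ground truth.

    Reports colony-identification accuracy, growth-call precision and
    recall, and novelty-call accuracy, each in [0, 1].
    """
    run_dir = Path(run_dir)
    if isinstance(ground_truth, (str, Path)):
        truth = sim.GroundTruth.from_json(ground_truth)
    else:
        truth = ground_truth
    if not truth.sample_composition:
        raise ValueError("ground truth is empty")
    reps = read_fasta(run_dir / "representatives.fasta")
    otu_taxon = _map_otus_to_taxa(reps, truth.templates)

    rows = []

    # colony identification
    ca_path = run_dir / "colony_assignments.tsv"
    if ca_path.exists() and truth.colony_taxon:
        ca = pd.read_csv(ca_path, sep="\t")
        correct = total = 0
        for row in ca.itertuples(index=False):
            true_taxon = truth.colony_taxon.get(row.colony_id)
            if true_taxon is None:
                continue
            total += 1
            if isinstance(row.assigned, str) and row.assigned:
                if otu_taxon.get(row.assigned) == true_taxon:
                    correct += 1
        if total:
            rows.append({"metric": "colony_id_accuracy", "value": correct / total,
                         "n": total})

    # growth calls
    gc_path = run_dir / "growth_calls.tsv"
    if gc_path.exists() and truth.grown:
        gc = pd.read_csv(gc_path, sep="\t")
        tp = fp = fn = 0
        for sample, true_taxa in truth.grown.items():
            sub = gc[gc["sample"] == sample]
            predicted = {otu_taxon.get(r.otu_id) for r in sub[sub["grew"]].itertuples()}
            predicted.discard(None)
            true_set = set(true_taxa)
            tp += len(predicted & true_set)
            fp += len(predicted - true_set)
            fn += len(true_set - predicted)
        if tp + fp:
            rows.append({"metric": "growth_precision", "value": tp / (tp + fp),
                         "n": tp + fp})
        if tp + fn:
            rows.append({"metric": "growth_recall", "value": tp / (tp + fn),
                         "n": tp + fn})

    # novelty calls: expected from the planted divergence (identity 100 - d)
    nv_path = run_dir / "novelty.tsv"
    if nv_path.exists():
        nv = pd.read_csv(nv_path, sep="\t")
        correct = total = 0
        for row in nv.itertuples(index=False):
            taxon = otu_taxon.get(row.otu_id)
            if taxon is None:
                continue
            if taxon in truth.novel_members:
                expected = (100.0 - truth.novel_members[taxon][1]) <= 95.0
            else:
                expected = False
            total += 1
            correct += int(bool(row.is_novel) == expected)
        if total:
            rows.append({"metric": "novelty_accuracy", "value": correct / total,
                         "n": total})

    df = pd.DataFrame(rows)
    if len(df) and not df["value"].between(0, 1).all():
        raise AssertionError("validation metrics out of [0, 1]")
    df.to_csv(run_dir / "validation.tsv", sep="\t", index=False)
    return df
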