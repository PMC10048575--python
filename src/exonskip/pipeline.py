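"""End-to-end orchestration: count -> psi -> diff -> coding -> summaries.

A single :class:`PipelineConfig` collects input paths, the sample-to-group
map and all statistical parameters (defaults follow the target study:
49-nt reads, 82-nt junction window, 8-nt anchors, e = 0.01, FDR < 0.11,
total-instance filter 10, SJ coverage filter > 5, AS2/NMD abundance
thresholds 4 and 2).  Outputs are TSVs so stages compose on disk, plus a
manifest echoing every parameter for reproducibility.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .counting import count_samples, effective_lengths
from .events import events_to_frame, frame_to_events, read_gene_models
from .io import (
    read_counts_tsv,
    read_deg_tsv,
    read_genome_fasta,
    read_protein_fasta,
    write_counts_tsv,
)
from .model import DifferentialSplicing, psi_point_estimate
from .coding import classify_events
from . import summaries as summ

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, group design and parameters of one pipeline run."""

    out_dir: str
    groups: Mapping[str, str] = field(default_factory=dict)  # sample -> group
    gtf: str | None = None
    genome_fasta: str | None = None
    protein_fasta: str | None = None
    sam_files: Mapping[str, str] = field(default_factory=dict)  # sample -> SAM path
    counts_tsv: str | None = None
    known_bed: str | None = None
    deg_tsv: str | None = None
    read_length: int = 49
    junction_length: int = 82
    anchor_length: int = 8
    e: float = 0.01
    fdr_threshold: float = 0.11
    min_total_instances: int = 10
    min_sj_coverage: int = 5
    as2_min: int = 4
    nmd_min: int = 2
    sigma_floor: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("no sample-to-group assignments given")
        group_names = sorted(set(self.groups.values()))
        if len(group_names) < 2:
            raise ValueError(f"need at least two groups, got {group_names}")
        for g in group_names:
            if not any(v == g for v in self.groups.values()):
                raise ValueError(f"group {g} has no samples")
        if self.counts_tsv is None:
            if not self.sam_files:
                raise ValueError("provide either counts_tsv or sam_files")
            if self.gtf is None:
                raise ValueError("SAM input requires a GTF of gene models")
            missing = [s for s in self.groups if s not in self.sam_files]
            if missing:
                raise ValueError(f"samples without SAM files: {missing}")
        for label, path in [
            ("gtf", self.gtf),
            ("genome_fasta", self.genome_fasta),
            ("protein_fasta", self.protein_fasta),
            ("counts_tsv", self.counts_tsv),
            ("known_bed", self.known_bed),
            ("deg_tsv", self.deg_tsv),
            *[(f"sam[{s}]", p) for s, p in self.sam_files.items()],
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")
        for name in ("read_length", "junction_length", "anchor_length",
                     "min_total_instances", "min_sj_coverage", "as2_min", "nmd_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def comparisons(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(sorted(set(self.groups.values())), 2))


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute all stages; returns a bundle of the in-memory tables.

    Writes events, counts, per-sample psi, per-comparison differential
    results, coding calls, summary tables and a run manifest under
    ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lengths = effective_lengths(config.read_length, config.junction_length, config.anchor_length)

    # --- events and counts -------------------------------------------------
    if config.counts_tsv is not None:
        events_frame, counts = read_counts_tsv(config.counts_tsv)
        logger.info("loaded %d events from %s", len(events_frame), config.counts_tsv)
    else:
        genes = read_gene_models(config.gtf)
        from .events import enumerate_es_events

        events = enumerate_es_events(genes)
        events_frame = events_to_frame(events)
        counts = count_samples(
            {s: config.sam_files[s] for s in sorted(config.groups)},
            events,
            anchor_length=config.anchor_length,
        )
        logger.info("counted %d events x %d samples", len(events), len(config.groups))
    write_counts_tsv(events_frame, counts, out / "counts.tsv")

    # --- total-instance filter ---------------------------------------------
    kept = summ.filter_events(counts, config.min_total_instances)
    events_frame = events_frame[events_frame["event_id"].isin(kept)].reset_index(drop=True)
    counts = counts[counts["event_id"].isin(kept)].reset_index(drop=True)
    logger.info("%d events pass the total-instance filter (>= %d)",
                len(events_frame), config.min_total_instances)

    # --- per-sample psi ----------------------------------------------------
    psi = counts.copy()
    psi["psi"] = psi_point_estimate(psi["I"].to_numpy(), psi["S"].to_numpy(), lengths)
    psi[["event_id", "sample_id", "I", "S", "psi"]].to_csv(
        out / "psi.tsv", sep="\t", index=False
    )

    # --- differential splicing per group pair ------------------------------
    results_by_pair: dict[tuple[str, str], pd.DataFrame] = {}
    significant_sets: dict[str, set[str]] = {}
    for g1, g2 in config.comparisons():
        model = DifferentialSplicing(
            counts,
            groups=config.groups,
            group_pair=(g1, g2),
            lengths=lengths,
            e=config.e,
            sigma_floor=config.sigma_floor,
        )
        res = model.fit()
        label = f"{g1}_vs_{g2}"
        results_by_pair[(g1, g2)] = res.frame
        significant_sets[label] = set(res.significant(config.fdr_threshold)["event_id"])
        res.frame.to_csv(out / f"diff_{label}.tsv", sep="\t", index=False)
        logger.info("%s: %d significant events (FDR < %g)",
                    label, len(significant_sets[label]), config.fdr_threshold)

    # --- coding classification ---------------------------------------------
    coding_calls = None
    if config.genome_fasta and config.protein_fasta:
        genome = read_genome_fasta(config.genome_fasta)
        proteins = read_protein_fasta(config.protein_fasta)
        eligible = summ.coverage_filter_for_coding(counts, config.min_sj_coverage)
        coding_events = frame_to_events(
            events_frame[events_frame["event_id"].isin(eligible)]
        )
        coding_calls = classify_events(coding_events, genome, proteins)
        coding_calls.to_csv(out / "coding_calls.tsv", sep="\t", index=False)
        logger.info("classified %d events for coding potential", len(coding_calls))

    # --- summaries ----------------------------------------------------------
    summary_tables: dict[str, object] = {}
    known = None
    if config.known_bed:
        known = summ.annotate_known(events_frame, summ.read_known_bed(config.known_bed))
        annotated = events_frame.assign(known=known.to_numpy())
        annotated.to_csv(out / "events_annotated.tsv", sep="\t", index=False)
        summary_tables["known"] = annotated
    if len(significant_sets) >= 2:
        repl = summ.replicability_matrix(significant_sets)
        repl.to_csv(out / "replicability.tsv", sep="\t")
        summary_tables["replicability"] = repl
    if coding_calls is not None:
        sig_by_comp = {
            label: ids & set(coding_calls["event_id"])
            for label, ids in significant_sets.items()
        }
        tallies = summ.tally_coding_classes(coding_calls, sig_by_comp)
        tallies.to_csv(out / "coding_tallies.tsv", sep="\t", index=False)
        summary_tables["tallies"] = tallies
        ratio = summ.isoform_ratio_distribution(
            counts, lengths, event_ids=coding_calls["event_id"]
        )
        ratio.log2_ratios.rename("log2_long_over_skipped").to_csv(
            out / "isoform_ratio.tsv", sep="\t"
        )
        summary_tables["ratio"] = ratio
        as2_genes, nmd_genes = summ.abundance_lists(
            coding_calls, config.as2_min, config.nmd_min
        )
        pd.DataFrame({"gene_id": as2_genes}).to_csv(
            out / "as2_abundant_genes.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene_id": nmd_genes}).to_csv(
            out / "nmd_abundant_genes.tsv", sep="\t", index=False
        )
        summary_tables["abundance"] = (as2_genes, nmd_genes)
        fam_input = events_frame.merge(
            coding_calls[["event_id"]], on="event_id"
        )
        families = summ.gene_family_stats(fam_input)
        families.to_csv(out / "gene_families.tsv", sep="\t", index=False)
        summary_tables["families"] = families
    if config.deg_tsv:
        deg = read_deg_tsv(config.deg_tsv)
        das_events = set().union(*significant_sets.values()) if significant_sets else set()
        das_genes = events_frame.loc[
            events_frame["event_id"].isin(das_events), "gene_name"
        ].unique()
        overlap = summ.das_deg_overlap(das_genes, deg)
        pd.DataFrame({"gene": overlap}).to_csv(
            out / "das_deg_overlap.tsv", sep="\t", index=False
        )
        summary_tables["das_deg_overlap"] = overlap

    manifest = {
        "exonskip_version": __version__,
        "python": sys.version.split()[0],
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("groups", "sam_files")
        },
        "groups": dict(config.groups),
        "comparisons": [f"{a}_vs_{b}" for a, b in config.comparisons()],
        "effective_lengths": {"l_inclusion": lengths.l_inclusion, "l_skip": lengths.l_skip},
        "n_events": int(len(events_frame)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "events": events_frame,
        "counts": counts,
        "psi": psi,
        "results": results_by_pair,
        "significant": significant_sets,
        "coding_calls": coding_calls,
        "summaries": summary_tables,
        "manifest": manifest,
    }
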