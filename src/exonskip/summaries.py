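"""Event filters and downstream summary tables.

Filters follow strict boundary semantics: an event is retained when its
total junction instances across all samples reach 10 ("less than 10" are
dropped), and enters the coding tallies only when its skipping-junction
coverage exceeds 5 reads.  Summaries cover known-cassette-exon annotation,
AS2/NMD class tallies, the long/skipped expression log-ratio distribution,
gene-family aggregation by symbol prefix, cross-comparison replicability of
significant events, per-gene AS2/NMD abundance lists, and the overlap of
differentially spliced genes with an external DEG list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_TOTAL_INSTANCES = 10
DEFAULT_MIN_SJ_COVERAGE = 5
DEFAULT_FDR_THRESHOLD = 0.11
DEFAULT_AS2_MIN = 4
DEFAULT_NMD_MIN = 2

#: Family labels that extend beyond the default three leading characters.
FAMILY_ALIASES = ("Tmem",)


def filter_events(
    counts: pd.DataFrame,
    min_total_instances: int = DEFAULT_MIN_TOTAL_INSTANCES,
    instances: str = "inclusion_plus_skipping",
) -> pd.Index:
    """Event ids whose total junction instances reach the threshold.

    ``instances`` selects what counts as an instance: inclusion plus
    skipping reads (default) or skipping-junction reads only.
    """
    if instances == "inclusion_plus_skipping":
        totals = counts.groupby("event_id")[["I", "S"]].sum().sum(axis=1)
    elif instances == "skipping_only":
        totals = counts.groupby("event_id")["S"].sum()
    else:
        raise ValueError(f"unknown instances mode {instances!r}")
    return totals.index[totals >= min_total_instances]


def coverage_filter_for_coding(
    counts: pd.DataFrame, min_sj_coverage: int = DEFAULT_MIN_SJ_COVERAGE
) -> pd.Index:
    """Event ids whose skip-junction total strictly exceeds the threshold."""
    sj = counts.groupby("event_id")["S"].sum()
    return sj.index[sj > min_sj_coverage]


def annotate_known(events: pd.DataFrame, known_bed: pd.DataFrame | None) -> pd.Series:
    """Flag events whose target exon exactly matches an annotated cassette exon.

    ``known_bed`` holds BED-style columns (chrom, start, end, strand,
    0-based half-open); a missing or empty annotation marks every event
    novel.  The match is exact on (chrom, start, end, strand).
    """
    if known_bed is None or len(known_bed) == 0:
        return pd.Series(False, index=events.index, name="known")
    keys = set(
        zip(known_bed["chrom"], known_bed["start"], known_bed["end"], known_bed["strand"])
    )
    flags = [
        (row.chrom, row.target_start, row.target_end, row.strand) in keys
        for row in events.itertuples(index=False)
    ]
    return pd.Series(flags, index=events.index, name="known")


def read_known_bed(path: str) -> pd.DataFrame:
    """Read a knownAlt-style BED (chrom, start, end, name, score, strand)."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return bed


def tally_coding_classes(
    coding_calls: pd.DataFrame,
    significant_sets: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Long/Both/Skipped/neither tallies, overall or per comparison.

    ``coding_calls`` needs ``event_id``, ``gene_id`` and ``event_class``
    columns.  With ``significant_sets`` (comparison label -> significant
    event ids) one row per comparison is produced plus a ``merged`` row
    counting unique genes across comparisons once.
    """
    calls = coding_calls.set_index("event_id")

    def _tally(event_ids: Iterable[str] | None, label: str) -> dict:
        sub = calls if event_ids is None else calls.loc[calls.index.intersection(list(event_ids))]
        cls = sub["event_class"]
        return {
            "comparison": label,
            "long": int((cls == "long_only").sum()),
            "both": int((cls == "AS2").sum()),
            "skipped": int((cls == "skipped_only").sum()),
            "neither": int((cls == "neither").sum()),
            "total": int(len(sub)),
            "n_genes": int(sub["gene_id"].nunique()),
        }

    if significant_sets is None:
        return pd.DataFrame([_tally(None, "all")])
    rows = [_tally(ids, label) for label, ids in significant_sets.items()]
    merged_ids = set().union(*[set(ids) for ids in significant_sets.values()])
    rows.append(_tally(merged_ids, "merged"))
    return pd.DataFrame(rows)


@dataclass
class RatioDistribution:
    """Pooled long/skipped expression log-ratios over eligible events."""

    log2_ratios: pd.Series  # finite values only, indexed by event_id
    n_infinite: int
    mean: float
    mode: float


def isoform_ratio_distribution(
    counts: pd.DataFrame,
    lengths,
    event_ids: Iterable[str] | None = None,
    bin_width: float = 0.5,
) -> RatioDistribution:
    """Per-event log2 of length-normalized long/skipped expression.

    Pools counts over samples: log2((sum I / l_I) / (sum S / l_S)).  A zero
    count on either side makes the ratio infinite; such events are flagged
    and excluded from the mean and histogram mode.
    """
    sub = counts if event_ids is None else counts[counts["event_id"].isin(set(event_ids))]
    pooled = sub.groupby("event_id")[["I", "S"]].sum()
    with np.errstate(divide="ignore"):
        ratio = np.log2(
            (pooled["I"] / lengths.l_inclusion) / (pooled["S"] / lengths.l_skip)
        )
    finite = ratio[np.isfinite(ratio)]
    n_inf = int(len(ratio) - len(finite))
    if len(finite) == 0:
        return RatioDistribution(finite, n_inf, float("nan"), float("nan"))
    lo = np.floor(finite.min() / bin_width) * bin_width
    hi = np.ceil(finite.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, edges = np.histogram(finite, bins=edges)
    mode = float(edges[int(np.argmax(hist))] + bin_width / 2)
    return RatioDistribution(
        log2_ratios=finite,
        n_infinite=n_inf,
        mean=float(finite.mean()),
        mode=mode,
    )


def gene_family(symbol: str, aliases: Sequence[str] = FAMILY_ALIASES) -> str:
    """Family label of a gene symbol: a shipped multi-letter alias when one
    matches, else the three first letters (case-normalized)."""
    norm = symbol.strip().capitalize()
    for alias in sorted(aliases, key=len, reverse=True):
        if norm.lower().startswith(alias.lower()):
            return alias
    return norm[:3]


def gene_family_stats(
    events: pd.DataFrame,
    aliases: Sequence[str] = FAMILY_ALIASES,
) -> pd.DataFrame:
    """Aggregate ES events per gene family (3-letter symbol prefix).

    ``events`` needs ``gene_name`` and ``event_id`` columns and optionally
    ``fdr``.  Families report number of distinct genes, number of ES
    events, the minimum FDR and the gene carrying it, sorted by descending
    gene count then event count.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=["family", "n_genes", "n_es", "min_fdr", "top_gene"])
    work = events.copy()
    work["family"] = work["gene_name"].map(lambda s: gene_family(s, aliases))
    if "fdr" not in work.columns:
        work["fdr"] = np.nan
    rows = []
    for family, grp in work.groupby("family"):
        if grp["fdr"].notna().any():
            imin = grp["fdr"].idxmin()
            min_fdr = float(grp.loc[imin, "fdr"])
            top_gene = str(grp.loc[imin, "gene_name"])
        else:
            min_fdr = float("nan")
            top_gene = str(grp["gene_name"].iloc[0])
        rows.append(
            {
                "family": family,
                "n_genes": int(grp["gene_name"].nunique()),
                "n_es": int(grp["event_id"].nunique()),
                "min_fdr": min_fdr,
                "top_gene": top_gene,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["n_genes", "n_es", "family"], ascending=[False, False, True]
    ).reset_index(drop=True)


def replicability_matrix(significant_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Shared significant-event counts between comparisons.

    Diagonal entries are per-comparison totals; off-diagonals count events
    (by identity key) shared between two comparisons.  Symmetric by
    construction.
    """
    labels = list(significant_sets)
    if len(labels) < 2:
        raise ValueError("replicability needs at least two comparisons")
    sets = {label: set(ids) for label, ids in significant_sets.items()}
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for a in labels:
        for b in labels:
            mat.loc[a, b] = len(sets[a] & sets[b]) if a != b else len(sets[a])
    return mat


def abundance_lists(
    coding_calls: pd.DataFrame,
    as2_min: int = DEFAULT_AS2_MIN,
    nmd_min: int = DEFAULT_NMD_MIN,
) -> tuple[list[str], list[str]]:
    """Genes rich in AS2 events and genes rich in NMD events.

    AS2-abundant genes carry at least ``as2_min`` events with both isoforms
    coding; NMD-abundant genes at least ``nmd_min`` events where exactly
    one isoform is coding.
    """
    as2 = coding_calls[coding_calls["event_class"] == "AS2"]
    nmd = coding_calls[coding_calls["event_class"].isin(["long_only", "skipped_only"])]
    as2_counts = as2.groupby("gene_id")["event_id"].nunique()
    nmd_counts = nmd.groupby("gene_id")["event_id"].nunique()
    return (
        sorted(as2_counts.index[as2_counts >= as2_min]),
        sorted(nmd_counts.index[nmd_counts >= nmd_min]),
    )


def das_deg_overlap(das_genes: Iterable[str], deg_table: pd.DataFrame,
                    gene_column: str = "gene") -> list[str]:
    """Case-normalized intersection of DAS genes with a DEG list."""
    if len(deg_table) == 0:
        return []
    das = {str(g).strip().lower() for g in das_genes}
    degs = {str(g).strip().lower() for g in deg_table[gene_column]}
    return sorted(das & degs)
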