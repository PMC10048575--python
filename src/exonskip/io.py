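"""On-disk TSV schemas shared by the pipeline stages.

The junction-count table is wide: one row per event with its coordinates
(0-based half-open) followed by per-sample ``<sample>_I`` and ``<sample>_S``
columns.  Results and coding-call tables are flat TSVs whose column
semantics mirror rMATS output (IncLevel1/IncLevel2/IncLevelDifference/
PValue/FDR) under our own names.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .events import EVENT_COLUMNS


def write_counts_tsv(events: pd.DataFrame, counts: pd.DataFrame, path: str | Path) -> None:
    """Write the wide per-event junction-count table.

    ``events`` is the event coordinate frame (see events.EVENT_COLUMNS);
    ``counts`` is long format with event_id/sample_id/I/S.
    """
    samples = sorted(counts["sample_id"].unique())
    wide = events.set_index("event_id")[EVENT_COLUMNS[1:]].copy()
    pivot_I = counts.pivot_table(index="event_id", columns="sample_id", values="I", aggfunc="sum")
    pivot_S = counts.pivot_table(index="event_id", columns="sample_id", values="S", aggfunc="sum")
    for s in samples:
        wide[f"{s}_I"] = pivot_I[s].reindex(wide.index).fillna(0).astype(int)
        wide[f"{s}_S"] = pivot_S[s].reindex(wide.index).fillna(0).astype(int)
    wide.reset_index().to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the wide counts table back into (events, long counts)."""
    wide = pd.read_csv(path, sep="\t")
    events = wide[[c for c in EVENT_COLUMNS if c in wide.columns]].copy()
    return events, counts_wide_to_long(wide)


def counts_wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    samples = sorted(
        {c[:-2] for c in wide.columns if c.endswith("_I") and f"{c[:-2]}_S" in wide.columns}
    )
    rows = []
    for s in samples:
        sub = pd.DataFrame(
            {
                "event_id": wide["event_id"],
                "sample_id": s,
                "I": wide[f"{s}_I"].astype(int),
                "S": wide[f"{s}_S"].astype(int),
            }
        )
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_coding_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_coding_calls_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_protein_fasta(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Protein FASTA indexed by gene: headers carry ``gene_id=<id>``."""
    from Bio import SeqIO

    proteins: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        for token in rec.description.split():
            if token.startswith("gene_id="):
                gene_id = token.split("=", 1)[1]
        proteins.setdefault(gene_id, []).append((rec.id, str(rec.seq)))
    return proteins


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_deg_tsv(path: str | Path, gene_column: str = "gene") -> pd.DataFrame:
    deg = pd.read_csv(path, sep="\t")
    if gene_column not in deg.columns:
        raise ValueError(f"DEG table lacks a {gene_column!r} column")
    return deg


def read_group_map(assignments: Mapping[str, str] | Sequence[str]) -> dict[str, str]:
    """Normalize group assignments given as mapping or 'sample=group' tokens."""
    if isinstance(assignments, Mapping):
        return dict(assignments)
    mapping = {}
    for token in assignments:
        sample, _, group = token.partition("=")
        if not group:
            raise ValueError(f"bad group assignment {token!r}; expected sample=group")
        mapping[sample] = group
    return mapping
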