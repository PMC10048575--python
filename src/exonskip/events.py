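"""Gene models and cassette-exon (exon-skipping) event enumeration.

An exon-skipping (ES) event is a triplet of consecutive exons on a gene's
flattened exon chain: an upstream exon, a skippable internal "target"
(cassette) exon, and a downstream exon.  Events are enumerated per gene,
not per transcript: each gene's transcript exons are projected onto the
genome and merged into a single exon chain first, so one event exists per
consecutive internal exon regardless of how many transcripts share it.

All internal coordinates are 0-based half-open genomic intervals; GTF input
(1-based inclusive) is converted on read and on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

EVENT_COLUMNS = [
    "event_id",
    "gene_id",
    "gene_name",
    "chrom",
    "strand",
    "upstream_start",
    "upstream_end",
    "target_start",
    "target_end",
    "downstream_start",
    "downstream_end",
]


@dataclass
class GeneModel:
    """A gene's flattened exon chain on the genome.

    ``exons`` are non-overlapping 0-based half-open intervals in ascending
    genomic order, irrespective of strand; transcription order is ascending
    for '+' genes and descending for '-' genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    gene_name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping exons in flattened chain of {self.gene_id}")
        if not self.gene_name:
            self.gene_name = self.gene_id

    @property
    def exons_tx_order(self) -> list[Interval]:
        """Exons in transcription (5'->3' mRNA) order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class ESEvent:
    """One cassette-exon triplet.

    ``upstream_exon`` / ``downstream_exon`` are the transcriptionally
    upstream / downstream flanking exons, so on the '-' strand the upstream
    exon has the *larger* genomic coordinates.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    upstream_exon: Interval
    target_exon: Interval
    downstream_exon: Interval
    gene_name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        exons = [self.upstream_exon, self.target_exon, self.downstream_exon]
        if self.strand == "-":
            exons = exons[::-1]
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(
                    f"event {self.event_id}: exons must be disjoint and ordered "
                    f"along the genome consistently with strand {self.strand}"
                )

    @property
    def target_length(self) -> int:
        return self.target_exon[1] - self.target_exon[0]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals, merged where they touch or overlap."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def event_identifier(gene_id: str, chrom: str, target: Interval, strand: str) -> str:
    """Deterministic event id keyed on gene and target-exon coordinates."""
    return f"{gene_id}@{chrom}:{target[0]}-{target[1]}:{strand}"


def enumerate_es_events(genes: Iterable[GeneModel]) -> list[ESEvent]:
    """Enumerate one ES event per consecutive internal-exon triplet.

    Genes with fewer than three exons on the flattened chain carry no
    internal exon and are skipped with a log message (a single- or two-exon
    gene cannot host a cassette exon).
    """
    events: list[ESEvent] = []
    for gene in genes:
        chain = gene.exons_tx_order
        if len(chain) < 3:
            logger.info(
                "gene %s has %d exon(s) after flattening; no ES events",
                gene.gene_id,
                len(chain),
            )
            continue
        for i in range(1, len(chain) - 1):
            target = chain[i]
            events.append(
                ESEvent(
                    event_id=event_identifier(gene.gene_id, gene.chrom, target, gene.strand),
                    gene_id=gene.gene_id,
                    gene_name=gene.gene_name,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    upstream_exon=chain[i - 1],
                    target_exon=target,
                    downstream_exon=chain[i + 1],
                )
            )
    return events


def read_gene_models(gtf_path: str) -> list[GeneModel]:
    """Read a GTF file and flatten each gene's exons into a single chain."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gene_id = exon.attributes.get("gene_id", [exon.id])[0]
        gene_name = exon.attributes.get("gene_name", [gene_id])[0]
        rec = by_gene.setdefault(
            gene_id,
            {"chrom": exon.seqid, "strand": exon.strand, "name": gene_name, "exons": []},
        )
        # GTF is 1-based inclusive; gffutils keeps those coordinates.
        rec["exons"].append((exon.start - 1, exon.end))
    genes = [
        GeneModel(
            gene_id=gid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=merge_intervals(rec["exons"]),
            gene_name=rec["name"],
        )
        for gid, rec in by_gene.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str, source: str = "exonskip") -> None:
    """Write gene models as GTF (one transcript per gene, 1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in genes:
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}"; '
                f'transcript_id "{gene.gene_id}.t1";'
            )
            rows = [("gene", gene.start, gene.end), ("transcript", gene.start, gene.end)]
            rows += [("exon", s, e) for s, e in gene.exons]
            for feature, s, e in rows:
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            source,
                            feature,
                            str(s + 1),
                            str(e),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def events_to_frame(events: Sequence[ESEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "gene_name": ev.gene_name,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "upstream_start": ev.upstream_exon[0],
            "upstream_end": ev.upstream_exon[1],
            "target_start": ev.target_exon[0],
            "target_end": ev.target_exon[1],
            "downstream_start": ev.downstream_exon[0],
            "downstream_end": ev.downstream_exon[1],
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(frame: pd.DataFrame) -> list[ESEvent]:
    return [
        ESEvent(
            event_id=row.event_id,
            gene_id=row.gene_id,
            gene_name=getattr(row, "gene_name", row.gene_id),
            chrom=row.chrom,
            strand=row.strand,
            upstream_exon=(int(row.upstream_start), int(row.upstream_end)),
            target_exon=(int(row.target_start), int(row.target_end)),
            downstream_exon=(int(row.downstream_start), int(row.downstream_end)),
        )
        for row in frame.itertuples(index=False)
    ]
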