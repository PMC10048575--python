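"""Coding-potential checkup of exon-skipping events (AS2 vs NMD).

For each ES event two isoform segments are assembled in mRNA sense: the
included form (upstream + target + downstream exon) and the skipped form
(upstream + downstream).  Each segment is translated in the three forward
reading frames; a frame is *stop-free* when no stop codon occurs strictly
before its final codon.  An isoform is called protein-coding when some
stop-free frame's peptide is an exact substring of an annotated protein of
the same gene.

Event classes follow the two-isoform logic:

* ``AS2``           - both isoforms coding (two genuine protein products);
* ``long_only``     - only the included (long) isoform coding: skipping
                      introduces a premature termination codon (PTC) and
                      the skipped transcript is an NMD substrate;
* ``skipped_only``  - only the skipped isoform coding: the target exon
                      itself carries a PTC;
* ``neither``       - neither isoform coding (e.g. UTR-resident exons).

The NMD flag is set when exactly one isoform is coding.  The PTC criterion
is local to the three-exon window; the downstream exon-junction context
needed for the 50-nt NMD rule is outside this window and is deliberately
not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .events import ESEvent

logger = logging.getLogger(__name__)

_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
_STOP_CODONS = set(_TABLE.stop_codons)

CODING_CALL_COLUMNS = [
    "event_id",
    "gene_id",
    "included_coding",
    "skipped_coding",
    "included_frame",
    "skipped_frame",
    "matched_protein_id",
    "event_class",
    "nmd_flag",
]


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def translate_codons(sequence: str) -> str:
    """Translate complete codons with the standard code.

    Codons containing any non-ACGT character translate to ``X`` and are
    never treated as stops.
    """
    seq = sequence.upper()
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _STOP_CODONS:
            aas.append("*")
        else:
            aas.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


@dataclass(frozen=True)
class FrameScan:
    """Result of translating one reading frame of a segment."""

    frame: int
    stop_free: bool
    peptide: str


def assemble_isoform_sequence(
    event: ESEvent, genome: Mapping[str, str], which: str
) -> str:
    """mRNA-sense sequence of the included (triplet) or skipped (duplet) form.

    Exon sequences are concatenated in transcription order; minus-strand
    events are reverse-complemented so the output always reads 5'->3' on
    the mRNA.
    """
    if which not in ("included", "skipped"):
        raise ValueError("which must be 'included' or 'skipped'")
    try:
        chrom_seq = genome[event.chrom]
    except KeyError:
        raise KeyError(f"chromosome {event.chrom!r} absent from genome") from None
    exons = [event.upstream_exon, event.target_exon, event.downstream_exon]
    if which == "skipped":
        exons = [event.upstream_exon, event.downstream_exon]
    for start, end in exons:
        if not (0 <= start < end <= len(chrom_seq)):
            raise ValueError(
                f"event {event.event_id}: exon ({start}, {end}) outside "
                f"{event.chrom} (length {len(chrom_seq)})"
            )
    if event.strand == "+":
        return "".join(chrom_seq[s:e] for s, e in exons)
    # Transcription order on '-' runs right-to-left along the genome.
    return "".join(reverse_complement(chrom_seq[s:e]) for s, e in exons)


def three_frame_orf_scan(sequence: str) -> list[FrameScan]:
    """Translate a segment in the three forward frames.

    A frame is stop-free when no stop codon occurs strictly before its
    final codon (a terminal stop is allowed); the peptide is the
    translation truncated at the first stop, if any.
    """
    if len(sequence) < 3:
        raise ValueError("sequence must be at least one codon long")
    scans = []
    for frame in range(3):
        aa = translate_codons(sequence[frame:])
        stop_free = "*" not in aa[:-1]
        peptide = aa.split("*")[0]
        scans.append(FrameScan(frame=frame, stop_free=stop_free, peptide=peptide))
    return scans


@dataclass(frozen=True)
class IsoformVerdict:
    """Coding verdict for one isoform of one event."""

    coding: bool | None  # None = unevaluable (gene missing from protein set)
    frame: int | None = None
    protein_id: str | None = None


def match_annotated_protein(
    scans: Sequence[FrameScan],
    proteins_by_gene: Mapping[str, Sequence[tuple[str, str]]],
    gene_id: str,
) -> IsoformVerdict:
    """Call an isoform coding iff a stop-free frame matches an annotated protein.

    The peptide of a stop-free frame must be an exact substring of one of
    the gene's annotated proteins; ties between frames resolve to the
    lowest frame index.  A gene absent from the protein set yields an
    unevaluable verdict.
    """
    proteins = proteins_by_gene.get(gene_id)
    if not proteins:
        logger.warning("gene %s absent from protein set; verdict unevaluable", gene_id)
        return IsoformVerdict(coding=None)
    for scan in sorted(scans, key=lambda s: s.frame):
        if not scan.stop_free or not scan.peptide:
            continue
        for protein_id, protein_seq in proteins:
            if scan.peptide in protein_seq:
                return IsoformVerdict(coding=True, frame=scan.frame, protein_id=protein_id)
    return IsoformVerdict(coding=False)


@dataclass(frozen=True)
class CodingCall:
    """Per-event coding classification of both isoforms."""

    event_id: str
    included_coding: bool
    skipped_coding: bool
    included_frame: int | None = None
    skipped_frame: int | None = None
    matched_protein_id: str | None = None
    gene_id: str = ""

    @property
    def event_class(self) -> str:
        if self.included_coding and self.skipped_coding:
            return "AS2"
        if self.included_coding:
            return "long_only"
        if self.skipped_coding:
            return "skipped_only"
        return "neither"

    @property
    def nmd_flag(self) -> bool:
        return self.included_coding != self.skipped_coding


def classify_event(
    event_id: str,
    included: IsoformVerdict,
    skipped: IsoformVerdict,
    gene_id: str = "",
) -> CodingCall:
    """Combine the two isoform verdicts into an AS2/NMD class."""
    if included.coding is None or skipped.coding is None:
        raise ValueError(f"event {event_id}: isoform verdict unevaluable")
    return CodingCall(
        event_id=event_id,
        included_coding=included.coding,
        skipped_coding=skipped.coding,
        included_frame=included.frame,
        skipped_frame=skipped.frame,
        matched_protein_id=included.protein_id or skipped.protein_id,
        gene_id=gene_id,
    )


def classify_events(
    events: Sequence[ESEvent],
    genome: Mapping[str, str],
    proteins_by_gene: Mapping[str, Sequence[tuple[str, str]]],
) -> pd.DataFrame:
    """Classify a batch of events; unevaluable genes are flagged, not fatal."""
    rows = []
    for event in events:
        incl = match_annotated_protein(
            three_frame_orf_scan(assemble_isoform_sequence(event, genome, "included")),
            proteins_by_gene,
            event.gene_id,
        )
        skip = match_annotated_protein(
            three_frame_orf_scan(assemble_isoform_sequence(event, genome, "skipped")),
            proteins_by_gene,
            event.gene_id,
        )
        if incl.coding is None or skip.coding is None:
            rows.append(
                {
                    "event_id": event.event_id,
                    "gene_id": event.gene_id,
                    "included_coding": pd.NA,
                    "skipped_coding": pd.NA,
                    "included_frame": pd.NA,
                    "skipped_frame": pd.NA,
                    "matched_protein_id": None,
                    "event_class": "unevaluable",
                    "nmd_flag": False,
                }
            )
            continue
        call = classify_event(event.event_id, incl, skip, gene_id=event.gene_id)
        rows.append(
            {
                "event_id": call.event_id,
                "gene_id": call.gene_id,
                "included_coding": call.included_coding,
                "skipped_coding": call.skipped_coding,
                "included_frame": call.included_frame,
                "skipped_frame": call.skipped_frame,
                "matched_protein_id": call.matched_protein_id,
                "event_class": call.event_class,
                "nmd_flag": call.nmd_flag,
            }
        )
    return pd.DataFrame(rows, columns=CODING_CALL_COLUMNS)
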