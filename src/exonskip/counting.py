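"""Splice-junction read counting for exon-skipping events.

Each ES event defines three exon-exon junctions on the genome:

* UJ - upstream exon -> target exon (inclusion),
* DJ - target exon -> downstream exon (inclusion),
* SJ - upstream exon -> downstream exon (skipping).

A spliced alignment supports a junction iff one of its CIGAR ``N`` gaps
matches the junction's donor/acceptor coordinates exactly and the read has
at least ``anchor_length`` aligned nucleotides on both sides of that gap.
Inclusion counts are I = UJ + DJ and skipping counts S = SJ; a short target
exon can let a single read span both UJ and DJ, in which case it increments
both.

The effective lengths used to normalize I and S to the exon inclusion level
derive from the single-end read length r and the junction window length j:
the inclusion form exposes two junctions (l_I = 2 * (j - r + 1)) and the
skip form one (l_S = j - r + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .events import ESEvent

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 49
DEFAULT_JUNCTION_LENGTH = 82
DEFAULT_ANCHOR_LENGTH = 8

#: CIGAR operation codes that consume reference bases.
_REF_OPS = {0, 2, 7, 8}  # M, D, =, X
_N_OP = 3

COUNT_COLUMNS = ["event_id", "sample_id", "UJ", "DJ", "SJ", "I", "S"]


@dataclass(frozen=True)
class EffectiveLengths:
    """Effective inclusion/skip form lengths for PSI normalization."""

    read_length: int
    junction_length: int
    anchor_length: int = DEFAULT_ANCHOR_LENGTH
    l_inclusion: int = 0
    l_skip: int = 0

    def __post_init__(self) -> None:
        if self.junction_length < self.read_length:
            raise ValueError(
                f"junction_length ({self.junction_length}) must be >= "
                f"read_length ({self.read_length})"
            )
        if self.anchor_length < 1:
            raise ValueError("anchor_length must be >= 1")
        l_s = self.junction_length - self.read_length + 1
        object.__setattr__(self, "l_skip", l_s)
        object.__setattr__(self, "l_inclusion", 2 * l_s)


def effective_lengths(
    read_length: int = DEFAULT_READ_LENGTH,
    junction_length: int = DEFAULT_JUNCTION_LENGTH,
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
) -> EffectiveLengths:
    """Effective lengths from read length r and junction window length j.

    l_I = 2 * (j - r + 1) and l_S = j - r + 1; with the defaults r=49, j=82
    this yields 68 and 34.
    """
    return EffectiveLengths(read_length, junction_length, anchor_length)


def event_junctions(event: ESEvent) -> dict[str, tuple[int, int]]:
    """Genomic (gap_start, gap_end) of the UJ, DJ and SJ junctions.

    Junction coordinates are strand-agnostic: the gap interval between the
    genomically left exon's end and the genomically right exon's start.  On
    the '-' strand the transcriptionally upstream exon is genomically to
    the right, so the roles are mapped accordingly.
    """
    up, tg, dn = event.upstream_exon, event.target_exon, event.downstream_exon
    if event.strand == "+":
        return {
            "UJ": (up[1], tg[0]),
            "DJ": (tg[1], dn[0]),
            "SJ": (up[1], dn[0]),
        }
    return {
        "UJ": (tg[1], up[0]),
        "DJ": (dn[1], tg[0]),
        "SJ": (dn[1], up[0]),
    }


def _spliced_segments(read: pysam.AlignedSegment) -> tuple[list[int], list[tuple[int, int]]]:
    """Aligned-segment reference lengths and the N gaps separating them.

    Returns ``(segment_lengths, gaps)`` where ``segment_lengths[i]`` and
    ``segment_lengths[i+1]`` flank ``gaps[i] = (gap_start, gap_end)``.
    """
    pos = read.reference_start
    seg_lengths = [0]
    gaps: list[tuple[int, int]] = []
    for op, length in read.cigartuples:
        if op == _N_OP:
            gaps.append((pos, pos + length))
            pos += length
            seg_lengths.append(0)
        elif op in _REF_OPS:
            seg_lengths[-1] += length
            pos += length
    return seg_lengths, gaps


def iter_alignments(source) -> Iterable[pysam.AlignedSegment]:
    """Yield mapped alignments from a SAM/BAM path or an iterable of records."""
    if isinstance(source, (str, Path)):
        with pysam.AlignmentFile(str(source), "r") as fh:
            for read in fh:
                yield read
    else:
        yield from source


def count_junction_reads(
    alignments,
    events: Sequence[ESEvent],
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Count UJ/DJ/SJ junction-spanning reads for one sample.

    ``alignments`` may be a SAM/BAM path or an iterable of pysam records
    (all belonging to the same sample).  Every event is reported, with zero
    counts where no read supports it.  Reads on other chromosomes or with
    junctions not matching any event are ignored; reads whose CIGAR is
    missing are skipped with a warning.
    """
    if anchor_length < 1:
        raise ValueError("anchor_length must be >= 1")
    lookup: dict[tuple[str, int, int], list[tuple[str, str]]] = {}
    for ev in events:
        for role, (gs, ge) in event_junctions(ev).items():
            lookup.setdefault((ev.chrom, gs, ge), []).append((ev.event_id, role))

    counts: dict[str, dict[str, int]] = {
        ev.event_id: {"UJ": 0, "DJ": 0, "SJ": 0} for ev in events
    }
    n_malformed = 0
    for read in iter_alignments(alignments):
        if read.is_unmapped:
            continue
        if read.cigartuples is None:
            n_malformed += 1
            continue
        chrom = read.reference_name
        seg_lengths, gaps = _spliced_segments(read)
        for i, gap in enumerate(gaps):
            if seg_lengths[i] < anchor_length or seg_lengths[i + 1] < anchor_length:
                continue
            for event_id, role in lookup.get((chrom, *gap), ()):
                counts[event_id][role] += 1
    if n_malformed:
        warnings.warn(f"skipped {n_malformed} read(s) with missing CIGAR", stacklevel=2)

    rows = []
    for ev in events:
        c = counts[ev.event_id]
        rows.append(
            {
                "event_id": ev.event_id,
                "sample_id": sample_id,
                "UJ": c["UJ"],
                "DJ": c["DJ"],
                "SJ": c["SJ"],
                "I": c["UJ"] + c["DJ"],
                "S": c["SJ"],
            }
        )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def count_samples(
    sample_alignments: Mapping[str, object],
    events: Sequence[ESEvent],
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
) -> pd.DataFrame:
    """Count junction reads for several samples (sample_id -> SAM path/records)."""
    frames = [
        count_junction_reads(source, events, anchor_length, sample_id=sample)
        for sample, source in sample_alignments.items()
    ]
    if not frames:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    return pd.concat(frames, ignore_index=True)
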