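"""Synthetic gene models, junction counts and spliced reads with known truth.

The generator emulates the statistical and reading-frame structure the
ES analysis assumes, at desk scale:

* genes with >= 3 exons on random strands, a clean CDS starting at an ATG
  at position 1 of exon 1 and ending in a stop codon in the last exon;
* one cassette-exon event per gene whose target-exon sequence is edited so
  the coding class of both isoforms is known by construction
  (``AS2`` / ``NMD_skipped_noncoding`` / ``NMD_included_noncoding`` /
  ``neither``), including frameshifting target lengths (e.g. 94 nt) that
  leave the skipped duplet without any stop-free reading frame;
* junction counts drawn per replicate r of group g as

      logit(psi_gr) ~ Normal(logit(psi_g), sigma^2)
      n_r ~ Poisson(coverage_mean),  I_r ~ Binomial(n_r, f(psi_gr)),

  with the effective-length normalized inclusion rate f; and
* single-end spliced SAM records spanning the UJ/DJ/SJ junctions with
  offsets uniform over the positions satisfying the anchor constraint, so
  junction counting round-trips the simulated (I, S) exactly.

Everything is deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.special import expit, logit

from .coding import reverse_complement, translate_codons
from .counting import effective_lengths, event_junctions
from .events import ESEvent, GeneModel, enumerate_es_events
from .model import PSI_EPS, normalized_inclusion

CODING_CLASSES = ("AS2", "NMD_skipped_noncoding", "NMD_included_noncoding", "neither")

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


class SyntheticConfigError(ValueError):
    """Invalid synthetic-dataset configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of a synthetic ES dataset.

    Defaults mirror the study design the analysis targets: six single-end
    replicates per group, 49-nt post-trim reads with an 82-nt junction
    window and 8-nt anchors, logit-scale replicate SD 0.1, and planted
    coding-class fractions 0.5 AS2 / 0.25 NMD-skipped / 0.25 NMD-included.
    """

    n_genes: int = 50
    exons_per_gene: int = 3
    exon_length_range: tuple[int, int] = (90, 150)
    intron_length_range: tuple[int, int] = (80, 200)
    coverage_mean: float = 100.0
    n_replicates_per_group: int = 6
    group_psi: tuple[float, ...] = (0.5, 0.5)
    sigma: float = 0.1
    frac_as2: float = 0.5
    frac_nmd_skip: float = 0.25
    frac_nmd_incl: float = 0.25
    read_length: int = 49
    junction_length: int = 82
    anchor_length: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SyntheticConfigError("n_genes must be positive")
        if self.exons_per_gene < 3:
            raise SyntheticConfigError("exons_per_gene must be >= 3 (cassette exon needs flanks)")
        lo, hi = self.exon_length_range
        # Flank anchors need read_length - anchor_length nt of exon on each side.
        min_exon = max(45, self.read_length - self.anchor_length + 1)
        if not (min_exon <= lo <= hi):
            raise SyntheticConfigError(
                f"exon_length_range must satisfy {min_exon} <= lo <= hi, got {self.exon_length_range}"
            )
        ilo, ihi = self.intron_length_range
        if not (10 <= ilo <= ihi):
            raise SyntheticConfigError("intron_length_range must satisfy 10 <= lo <= hi")
        if self.coverage_mean <= 0:
            raise SyntheticConfigError("coverage_mean must be positive")
        if self.n_replicates_per_group < 1:
            raise SyntheticConfigError("n_replicates_per_group must be positive")
        if len(self.group_psi) < 1 or any(not (0.0 <= p <= 1.0) for p in self.group_psi):
            raise SyntheticConfigError("group_psi values must lie in [0, 1]")
        if self.sigma < 0:
            raise SyntheticConfigError("sigma must be non-negative")
        fracs = (self.frac_as2, self.frac_nmd_skip, self.frac_nmd_incl)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise SyntheticConfigError("class fractions must lie in [0,1] and sum to <= 1")
        if self.read_length < 2 * self.anchor_length:
            raise SyntheticConfigError("read_length must be >= 2 * anchor_length")
        if self.junction_length < self.read_length:
            raise SyntheticConfigError("junction_length must be >= read_length")

    @property
    def group_names(self) -> list[str]:
        return [f"group{i + 1}" for i in range(len(self.group_psi))]

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{g}_r{r + 1}"
            for g in self.group_names
            for r in range(self.n_replicates_per_group)
        ]

    def sample_groups(self) -> dict[str, str]:
        return {
            f"{g}_r{r + 1}": g
            for g in self.group_names
            for r in range(self.n_replicates_per_group)
        }


@dataclass
class _GeneDraft:
    """mRNA-space draft of one gene before genome assembly."""

    gene_id: str
    strand: str
    exon_seqs: list[str]
    intron_seqs: list[str]
    coding_class: str = "AS2"
    proteins: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mrna(self) -> str:
        return "".join(self.exon_seqs)


@dataclass
class SyntheticGenome:
    """Gene model set, genome sequence and annotated proteins."""

    config: SyntheticConfig
    drafts: list[_GeneDraft]
    chrom: str = "chrS"
    genes: list[GeneModel] = field(default_factory=list)
    genome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            self.rebuild()

    @property
    def proteins(self) -> dict[str, list[tuple[str, str]]]:
        return {d.gene_id: list(d.proteins) for d in self.drafts}

    def rebuild(self) -> None:
        """Lay the gene drafts onto a single chromosome."""
        spacer_rng = np.random.default_rng([2, self.config.seed])
        parts: list[str] = []
        genes: list[GeneModel] = []
        cursor = 0
        for draft in self.drafts:
            gap = "".join(
                "ACGT"[i] for i in spacer_rng.integers(0, 4, size=100)
            )
            parts.append(gap)
            cursor += len(gap)
            pre_mrna_parts: list[str] = []
            offsets: list[tuple[int, int]] = []
            off = 0
            for i, exon in enumerate(draft.exon_seqs):
                offsets.append((off, off + len(exon)))
                pre_mrna_parts.append(exon)
                off += len(exon)
                if i < len(draft.intron_seqs):
                    pre_mrna_parts.append(draft.intron_seqs[i])
                    off += len(draft.intron_seqs[i])
            pre_mrna = "".join(pre_mrna_parts)
            length = len(pre_mrna)
            if draft.strand == "+":
                parts.append(pre_mrna)
                exons = [(cursor + s, cursor + e) for s, e in offsets]
            else:
                parts.append(reverse_complement(pre_mrna))
                exons = [(cursor + length - e, cursor + length - s) for s, e in offsets]
            genes.append(
                GeneModel(
                    gene_id=draft.gene_id,
                    chrom=self.chrom,
                    strand=draft.strand,
                    exons=sorted(exons),
                    gene_name=draft.gene_id,
                )
            )
            cursor += length
        self.genome = {self.chrom: "".join(parts)}
        self.genes = genes

    def es_events(self) -> list[ESEvent]:
        return enumerate_es_events(self.genes)

    def planted_events(self) -> list[ESEvent]:
        """The one truth-planted event per gene (middle internal exon)."""
        events = []
        k = self.config.exons_per_gene // 2
        for gene in self.genes:
            chain = gene.exons_tx_order
            from .events import event_identifier

            events.append(
                ESEvent(
                    event_id=event_identifier(gene.gene_id, gene.chrom, chain[k], gene.strand),
                    gene_id=gene.gene_id,
                    gene_name=gene.gene_name,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    upstream_exon=chain[k - 1],
                    target_exon=chain[k],
                    downstream_exon=chain[k + 1],
                )
            )
        return events


@dataclass
class SyntheticTruth:
    """Ground truth for planted events: coding class and group psi."""

    events: pd.DataFrame  # event_id, gene_id, strand, coding_class, psi_<group>
    sigma: float
    group_names: list[str]
    latent: pd.DataFrame | None = None  # event_id, sample_id, psi_latent

    def psi_matrix(self) -> pd.DataFrame:
        cols = [f"psi_{g}" for g in self.group_names]
        return self.events.set_index("event_id")[cols]


def expected_event_class(coding_class: str) -> str:
    """CodingCall.event_class implied by a planted truth class."""
    return {
        "AS2": "AS2",
        "NMD_skipped_noncoding": "long_only",
        "NMD_included_noncoding": "skipped_only",
        "neither": "neither",
    }[coding_class]


def _random_codon_seq(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _fresh_mrna(rng: np.random.Generator, total_len: int) -> str:
    """Clean CDS of the requested length: ATG + non-stop codons + TAA."""
    assert total_len % 3 == 0 and total_len >= 9
    return "ATG" + _random_codon_seq(rng, total_len // 3 - 2) + "TAA"


def generate_gene_models(config: SyntheticConfig) -> SyntheticGenome:
    """Generate gene models, genome sequence and per-gene reference proteins.

    Each gene's concatenated exons form a clean ORF from an ATG at position
    1 of exon 1 to a terminal stop in the last exon; the emitted protein is
    its translation.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([1, config.seed])
    lo, hi = config.exon_length_range
    ilo, ihi = config.intron_length_range
    drafts: list[_GeneDraft] = []
    width = max(4, len(str(config.n_genes)))
    for g in range(config.n_genes):
        gene_id = f"SYNG{g + 1:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = rng.integers(lo, hi + 1, size=config.exons_per_gene).tolist()
        total = sum(exon_lens)
        exon_lens[-1] += (3 - total % 3) % 3
        intron_lens = rng.integers(ilo, ihi + 1, size=config.exons_per_gene - 1).tolist()
        mrna = _fresh_mrna(rng, sum(exon_lens))
        exon_seqs = []
        off = 0
        for L in exon_lens:
            exon_seqs.append(mrna[off : off + L])
            off += L
        intron_seqs = ["GT" + _random_nt(rng, L - 4) + "AG" for L in intron_lens]
        protein = translate_codons(mrna).rstrip("*")
        drafts.append(
            _GeneDraft(
                gene_id=gene_id,
                strand=strand,
                exon_seqs=exon_seqs,
                intron_seqs=intron_seqs,
                proteins=[(f"{gene_id}.p1", protein)],
            )
        )
    return SyntheticGenome(config=config, drafts=drafts)


def _has_internal_stop(seq: str) -> bool:
    aa = translate_codons(seq)
    return "*" in aa[:-1]


def _all_frames_stopped(seq: str) -> bool:
    for frame in range(3):
        aa = translate_codons(seq[frame:])
        if "*" not in aa[:-1]:
            return False
    return True


def _aligned_positions(start: int, end: int, phase_of: int, margin: int = 6) -> list[int]:
    """Codon-start positions q in [start+margin, end-margin-3] with q %% 3 == phase_of."""
    first = start + margin
    first += (phase_of - first) % 3
    return list(range(first, end - margin - 2, 3))


def _plant_gene(draft: _GeneDraft, coding_class: str, config: SyntheticConfig,
                rng: np.random.Generator) -> None:
    """Edit a gene draft in place so the planted event has the given class."""
    k = config.exons_per_gene // 2  # internal target exon (exon 2 of 3)
    lens = [len(s) for s in draft.exon_seqs]
    t_len = lens[k]
    if coding_class in ("AS2", "NMD_included_noncoding"):
        t_len -= t_len % 3  # frame-preserving target
    else:
        if t_len % 3 == 0:
            t_len += int(rng.integers(1, 3))  # frameshifting target
    lens[k] = t_len
    total = sum(lens)
    lens[-1] += (3 - total % 3) % 3

    for _attempt in range(300):
        mrna = _fresh_mrna(rng, sum(lens))
        seqs = []
        off = 0
        for L in lens:
            seqs.append(mrna[off : off + L])
            off += L
        u0 = sum(lens[:k - 1]) if k > 0 else 0
        t0 = u0 + lens[k - 1]
        d0 = t0 + lens[k]
        chars = list(mrna)

        if coding_class in ("NMD_skipped_noncoding", "neither"):
            # Kill every reading frame of the skipped duplet:
            # misaligned stops in the upstream exon kill duplet frames 1 and 2;
            # a duplet-frame-0 stop planted in the downstream exon (shifted by
            # the frameshifting target length in mRNA coordinates) kills frame 0
            # while leaving the included coding frame intact.
            ok = True
            for shift in (1, 2):
                cands = _aligned_positions(max(u0, 3), t0, shift)
                if not cands:
                    ok = False
                    break
                q = int(rng.choice(cands))
                chars[q : q + 3] = "TAA"
            # Duplet coordinates: the downstream exon starts at t0 once the
            # target is removed; positions map back to mRNA by + target length.
            cands = _aligned_positions(t0, t0 + lens[k + 1], 0)
            if not cands or not ok:
                continue
            q3 = int(rng.choice(cands))
            chars[q3 + lens[k] : q3 + lens[k] + 3] = "TAA"

        if coding_class in ("NMD_included_noncoding", "neither"):
            # PTC inside the target exon, aligned to the mRNA coding frame.
            cands = _aligned_positions(t0, d0, 0)
            if not cands:
                continue
            q = int(rng.choice(cands))
            chars[q : q + 3] = "TAA"

        mrna_edit = "".join(chars)
        seqs = []
        off = 0
        for L in lens:
            seqs.append(mrna_edit[off : off + L])
            off += L
        skipped = mrna_edit[:t0] + mrna_edit[d0:]

        if coding_class == "AS2":
            if _has_internal_stop(mrna_edit) or _has_internal_stop(skipped):
                continue
            proteins = [
                (f"{draft.gene_id}.p1", translate_codons(mrna_edit).rstrip("*")),
                (f"{draft.gene_id}.p2", translate_codons(skipped).rstrip("*")),
            ]
        elif coding_class == "NMD_included_noncoding":
            if not _has_internal_stop(mrna_edit) or _has_internal_stop(skipped):
                continue
            proteins = [(f"{draft.gene_id}.p1", translate_codons(skipped).rstrip("*"))]
        elif coding_class == "NMD_skipped_noncoding":
            if _has_internal_stop(mrna_edit) or not _all_frames_stopped(skipped):
                continue
            proteins = [(f"{draft.gene_id}.p1", translate_codons(mrna_edit).rstrip("*"))]
        elif coding_class == "neither":
            if not _has_internal_stop(mrna_edit) or not _all_frames_stopped(skipped):
                continue
            truncated = translate_codons(mrna_edit).split("*")[0]
            if not truncated:
                continue
            proteins = [(f"{draft.gene_id}.p1", truncated)]
        else:
            raise ValueError(f"unknown coding class {coding_class!r}")

        draft.exon_seqs = seqs
        draft.coding_class = coding_class
        draft.proteins = proteins
        return
    raise RuntimeError(
        f"failed to plant class {coding_class} in gene {draft.gene_id} after 300 attempts"
    )


def plant_es_truth(synth: SyntheticGenome, config: SyntheticConfig | None = None) -> SyntheticTruth:
    """Assign and plant a coding class per gene; returns the ground truth.

    Class counts follow the configured fractions (remainder -> ``neither``);
    target-exon sequences and lengths are edited so the included/skipped
    coding status is known by construction, and the gene's annotated
    proteins are regenerated to match the coding isoform(s).
    """
    config = config or synth.config
    rng = np.random.default_rng([3, config.seed])
    n = len(synth.drafts)
    n_as2 = int(round(config.frac_as2 * n))
    n_skip = int(round(config.frac_nmd_skip * n))
    n_incl = int(round(config.frac_nmd_incl * n))
    n_as2, n_skip, n_incl = _cap_counts(n, n_as2, n_skip, n_incl)
    classes = (
        ["AS2"] * n_as2
        + ["NMD_skipped_noncoding"] * n_skip
        + ["NMD_included_noncoding"] * n_incl
        + ["neither"] * (n - n_as2 - n_skip - n_incl)
    )
    rng.shuffle(classes)
    for draft, cls in zip(synth.drafts, classes):
        _plant_gene(draft, cls, config, rng)
    synth.rebuild()

    rows = []
    for event, draft in zip(synth.planted_events(), synth.drafts):
        row = {
            "event_id": event.event_id,
            "gene_id": event.gene_id,
            "strand": event.strand,
            "coding_class": draft.coding_class,
        }
        for g, psi in zip(config.group_names, config.group_psi):
            row[f"psi_{g}"] = float(psi)
        rows.append(row)
    return SyntheticTruth(
        events=pd.DataFrame(rows),
        sigma=config.sigma,
        group_names=config.group_names,
    )


def _cap_counts(n: int, *counts: int) -> tuple[int, ...]:
    out = []
    left = n
    for c in counts:
        c = min(c, left)
        out.append(c)
        left -= c
    return tuple(out)


def simulate_junction_counts(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    psi_by_event: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw per-replicate junction counts under the binomial/logit-normal model.

    Returns a long table (event_id, sample_id, group, UJ, DJ, SJ, I, S) and
    stores the per-replicate latent psi values on ``truth.latent``.
    Inclusion reads split evenly between UJ and DJ (odd counts: UJ gets the
    extra).  psi values of 0 or 1 are clamped to [1e-6, 1 - 1e-6] before
    the logit only when sigma > 0.
    """
    rng = np.random.default_rng([4, config.seed])
    lengths = effective_lengths(config.read_length, config.junction_length, config.anchor_length)
    psi_frame = psi_by_event if psi_by_event is not None else truth.psi_matrix()
    rows = []
    latent_rows = []
    for event_id, psi_row in psi_frame.iterrows():
        for group in truth.group_names:
            psi_g = float(psi_row[f"psi_{group}"])
            for r in range(config.n_replicates_per_group):
                sample = f"{group}_r{r + 1}"
                if config.sigma > 0:
                    z = rng.normal(
                        logit(np.clip(psi_g, PSI_EPS, 1.0 - PSI_EPS)), config.sigma
                    )
                    psi_r = float(expit(z))
                    f = float(normalized_inclusion(psi_r, lengths))
                else:
                    psi_r = psi_g
                    f = float(normalized_inclusion(psi_g, lengths))
                n_reads = int(rng.poisson(config.coverage_mean))
                I = int(rng.binomial(n_reads, f)) if n_reads > 0 else 0
                S = n_reads - I
                rows.append(
                    {
                        "event_id": event_id,
                        "sample_id": sample,
                        "group": group,
                        "UJ": (I + 1) // 2,
                        "DJ": I // 2,
                        "SJ": S,
                        "I": I,
                        "S": S,
                    }
                )
                latent_rows.append(
                    {"event_id": event_id, "sample_id": sample, "psi_latent": psi_r}
                )
    truth.latent = pd.DataFrame(latent_rows)
    return pd.DataFrame(rows)


def simulate_spliced_reads(
    synth: SyntheticGenome,
    counts: pd.DataFrame,
    config: SyntheticConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, list[pysam.AlignedSegment]]:
    """Emit spliced single-end SAM records realizing the given counts.

    For each event and sample, UJ/DJ/SJ junction-spanning reads are placed
    with junction offsets uniform over the positions leaving at least
    ``anchor_length`` aligned nt on both sides.  Records validate against
    the generated genome.  When ``out_dir`` is given one SAM file per
    sample is written there.
    """
    config = config or synth.config
    if config.read_length < 2 * config.anchor_length:
        raise SyntheticConfigError("read_length must be >= 2 * anchor_length")
    rng = np.random.default_rng([5, config.seed])
    r_len, a_len = config.read_length, config.anchor_length
    chrom_seq = synth.genome[synth.chrom]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": synth.chrom, "LN": len(chrom_seq)}],
        }
    )
    events = {ev.event_id: ev for ev in synth.planted_events()}
    reads: dict[str, list[pysam.AlignedSegment]] = {
        s: [] for s in sorted(counts["sample_id"].unique())
    }
    for row in counts.itertuples(index=False):
        event = events[row.event_id]
        junctions = event_junctions(event)
        per_role = {"UJ": int(row.UJ), "DJ": int(row.DJ), "SJ": int(row.SJ)}
        for role in ("UJ", "DJ", "SJ"):
            gl, gr = junctions[role]
            for i in range(per_role[role]):
                x = int(rng.integers(a_len, r_len - a_len + 1))
                pos = gl - x
                y = r_len - x
                seg = pysam.AlignedSegment(header)
                seg.query_name = f"{row.sample_id}|{event.gene_id}|{role}|{i}"
                seg.flag = 0 if event.strand == "+" else 16
                seg.reference_id = 0
                seg.reference_start = pos
                seg.mapping_quality = 255
                seg.cigarstring = f"{x}M{gr - gl}N{y}M"
                seq = chrom_seq[pos : pos + x] + chrom_seq[gr : gr + y]
                seg.query_sequence = seq
                reads[row.sample_id].append(seg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, segs in reads.items():
            with pysam.AlignmentFile(str(out_dir / f"{sample}.sam"), "w", header=header) as fh:
                for seg in segs:
                    fh.write(seg)
    return reads


def write_genome_fasta(synth: SyntheticGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in synth.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_protein_fasta(synth: SyntheticGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for draft in synth.drafts:
            for pid, seq in draft.proteins:
                fh.write(f">{pid} gene_id={draft.gene_id}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    truth.events.to_csv(path, sep="\t", index=False)
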