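# Methods

## Event definition and junction counting

A cassette-exon (ES) event is a triplet of consecutive exons on a gene's
flattened exon chain — the union of the gene's transcript exons projected
onto the genome.  Working per gene rather than per transcript means one
event per skippable internal exon regardless of transcript multiplicity;
genes whose flattened chain has fewer than three exons host no internal
exon and are skipped with a log message.  Coordinates are 0-based
half-open internally; GTF (1-based inclusive) is converted at the
boundary.

A read supports a junction only when one of its CIGAR `N` gaps coincides
*exactly* with the junction's donor/acceptor coordinates and at least
`anchor_length` aligned nucleotides flank the gap on both sides.  Exact
matching is deliberate: junctions are defined by annotated exon ends, and
near-miss gaps (tandem splice-site "bleeding" of exon flanks) are thereby
excluded rather than absorbed.  A read whose gap structure spans both
inclusion junctions (possible only for targets shorter than
read_length − 2·anchor) increments UJ and DJ both; the identity
I = UJ + DJ is kept.

## Inclusion level and effective lengths

With single-end reads of length r and a junction window of length j, a
junction is visible from j − r + 1 read start positions.  The inclusion
form has two junctions, the skip form one:

    l_I = 2 (j − r + 1),     l_S = j − r + 1.

Defaults r = 49 and j = 82 give l_I = 68 and l_S = 34.  The inclusion
level is psi = (I/l_I) / (I/l_I + S/l_S) and the probability that a
junction read is an inclusion read is f(psi) = l_I psi / (l_I psi +
l_S (1 − psi)).  These are inverse-linked: f reduces to a constant shift
of log(l_I/l_S) on the logit scale, an identity the optimizer exploits
(logit f(psi) = logit psi + log 2 for the default configuration).

## The hierarchical differential-splicing model

Per event and group g, replicate r contributes

    z_gr = logit(psi_gr) ~ Normal(mu_g, sigma^2)
    I_gr ~ Binomial(I_gr + S_gr, f(psi_gr)).

The group likelihood *marginalizes* the latent z_gr by Gauss–Hermite
quadrature (31 nodes).  We do not maximize jointly over the latent
replicate levels: the joint objective is degenerate — at z_r = mu each
replicate contributes −log sigma, so the joint supremum diverges as
sigma → 0 and the variance estimate always collapses to its floor, which
ignores replicate overdispersion and inflates the test's false-positive
rate.  The marginal likelihood has a well-defined interior optimum and
yields a calibrated test (verified by simulation in the test suite).
Per-replicate inclusion levels are reported as posterior modes of z_r at
the fitted (mu, sigma); the per-replicate objective is strictly concave,
so a vectorized Newton iteration suffices.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `read_length` | 49 nt | post-trim single-end read length |
| `junction_length` | 82 nt | junction window width (exposed; fixed by the counting convention) |
| `anchor_length` | 8 nt | minimum aligned nt flanking a junction gap |
| `e` | 0.01 | inclusion-difference threshold of the null hypothesis |
| `sigma_floor` | 0.01 | lower bound of the logit-scale replicate SD (identifiability with few replicates) |
| `fdr_threshold` | 0.11 | significance cutoff on BH-adjusted p-values |

The two-group test is a likelihood-ratio test of H0: |psi_1 − psi_2| ≤ e
against the unconstrained alternative, with sigma shared between groups
under both hypotheses.  When the unconstrained estimate already satisfies
the constraint the statistic is zero; otherwise the null optimum lies on
the boundary |psi_1 − psi_2| = e.  That constrained profile can be
bimodal in mu_1 (a mode near each group's own optimum) and may require a
large sigma to absorb the group separation, so the null fit scans a
coarse (mu, sigma) grid — both boundary signs — and polishes the best
cell with L-BFGS-B.  p-values use the chi-square(1 df) tail; the
inequality constraint makes the test conservative for e > 0, and the
boundary effect is deliberately not corrected.  Type-I calibration is
assessed at e = 0 (the point null), where the chi-square reference is the
appropriate one; with the pipeline default e = 0.01 the test is strictly
more conservative by construction.  Benjamini–Hochberg adjustment is
applied per comparison over all tested events.

Numerical choices: psi values are clamped to [1e-6, 1 − 1e-6] before any
logit; mu is bounded to ±25 on the logit scale; sigma to
[sigma_floor, 5]; replicates with I + S = 0 are dropped from an event's
fit rather than imputed; an event with an all-empty group is reported
unconverged with a missing p-value; impossible observations (f → 1 with
S > 0) are capped at −1e12 log-likelihood rather than −inf.

## Coding-potential classification

The included (upstream + target + downstream) and skipped (upstream +
downstream) segments are assembled in mRNA sense (minus-strand events
reverse-complemented) and translated in the three forward frames with the
standard genetic code; codons containing non-ACGT characters translate to
`X` and never to a stop.  A frame is *stop-free* when no stop codon
occurs strictly before its final codon (a terminal stop is allowed).  An
isoform is *coding* when some stop-free frame's peptide is an exact
substring of an annotated protein of the same gene; frame ties resolve to
the lowest index, and genes missing from the protein set yield an
"unevaluable" verdict rather than a class.

Event classes: AS2 (both coding), long_only / skipped_only (exactly one
coding; NMD flag set), neither (UTR-resident candidates).  The PTC
criterion is local to the three-exon window: the 50-nt exon-junction rule
of NMD biology needs downstream context outside this window and is out of
scope, as are alignment-based (BLAST-like) protein matches — the match
tolerance is exact and configurable only in the sense that the caller can
supply any protein set.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical and reading-frame structure the
analysis assumes, with ground truth known by construction:

* Genes of ≥ 3 exons on random strands, a clean ORF from an ATG at
  position 1 of exon 1 to a terminal stop in the last exon; introns are
  GT..AG; one chromosome with 100-nt spacers.  Exon lengths default to
  90–150 nt, introns to 80–200 nt — compact but large enough that every
  junction read fits inside its two exons.
* One planted event per gene with class fractions 0.5 AS2 / 0.25
  NMD-skipped / 0.25 NMD-included (remainder "neither").  AS2 targets are
  frame-preserving (length ≡ 0 mod 3, no junction stop) and both isoform
  proteins are emitted.  NMD-skipped targets frameshift (length ≢ 0
  mod 3) and stops are planted so the skipped duplet terminates in *every*
  reading frame — misaligned stops in the upstream exon kill the two
  shifted frames, a duplet-frame-0 stop in the downstream exon (misaligned
  in the included mRNA, which stays clean) kills the third.  NMD-included
  targets carry an in-frame PTC and only the skipped protein is emitted.
* Junction counts per replicate: logit(psi_gr) ~ Normal(logit(psi_g),
  sigma²) with psi clamped to [1e-6, 1 − 1e-6] before the logit (the
  clamp is skipped when sigma = 0 so boundary psi values behave exactly);
  total depth Poisson(coverage_mean) — a stand-in, as the emulated study
  design specifies library-level rather than per-event depth; I binomial
  with success f(psi_gr); inclusion reads split evenly UJ/DJ with odd
  counts favoring UJ.
* Spliced reads: 49-nt single-end records whose junction offsets are
  uniform over the positions satisfying the anchor constraint, emitted as
  valid SAM against the generated genome.  Counting them recovers the
  simulated (I, S) exactly, which the tests assert.

Defaults mirror the emulated study design: six replicates per group,
sigma = 0.1 on the logit scale, mean event depth 100.

Not emulated: sequencing errors and quality scores, exonic/intronic
background reads, paired ends, non-ES splice classes, multi-isoform exon
structures beyond the flattened chain, and expression-level variation
between genes.  Passing tests therefore demonstrate correctness of the
counting, estimation and classification machinery under the model's own
assumptions — not robustness to alignment artifacts or annotation error
in real data.

## Test problem sizes

The simulation-backed checks run at desk scale: type-I error on 1,000
null events (true psi 0.5 in both groups, sigma 0.1, depth 100, 6 + 6
replicates) with power assessed on 200 events at |Δpsi| = 0.8; group-psi
recovery on 500 events at depth 200; coding-class recovery on a 200-gene
genome; round trips on 30–40-gene datasets.  Grid-search oracles
(trapezoid-integrated marginal likelihood on (mu, sigma) grids) verify
the fits on ≤ 3-replicate toy events.

## Known limitations

* The e-threshold null is tested against chi-square(1) without a boundary
  correction; for e > 0 reported p-values are conservative.
* sigma is shared between groups; strongly heteroscedastic groups are not
  modelled.
* Exact junction matching cannot discover unannotated splice sites; novel
  junctions simply do not count.
* The "neither" class conflates UTR-resident exons with doubly
  non-coding constructions; an annotation-based CDS overlap check is the
  caller's responsibility.
* Family aggregation by 3-letter symbol prefix (plus a small alias list,
  e.g. `Tmem`) is a heuristic; prefixes can merge unrelated genes.
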