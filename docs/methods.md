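# Methods

## The problem

Roughly a tenth of pathogenic loss-of-function variants in large disease
genes such as *NF1* act through RNA splicing and are missed or
misinterpreted by DNA-only diagnostics. Targeted RNA-seq of the gene panel
captures the transcripts directly, but the raw junction evidence needs a
normalization that (a) separates sample-specific aberrant events from
naturally occurring minor isoforms shared by everyone in the run, and (b)
stays stable across the enormous dynamic range of capture panels
(10^2–10^4 reads per junction). `splicenrich` implements that
normalization — a per-sample, per-junction *enrichment score* (ERS) with
pseudocount damping — together with the junction discovery, significance
testing and diagnostic interpretation layer around it.

## Junction discovery and counting

Splice events are keyed by (contig, first intron nucleotide, last intron
nucleotide), 1-based inclusive — the convention of STAR splice-junction
output (`AG|gu … ag|G`). Events are collected from the CIGAR `N` gaps of
primary alignments; secondary, supplementary (chimeric) and unmapped
records never contribute. Each sample is then counted against the union of
events discovered in *any* sample of the run, producing a dense matrix of

- `r` (congruent): alignment contains a gap exactly matching the event
  (indels elsewhere in the read are tolerated);
- `s` (spanning): alignment starts strictly before the first intron
  nucleotide and ends at or beyond it, whatever the read's own splicing.
  Strictness on the upstream side means a read beginning exactly at the
  intron carries no junction information and is not counted;
- `b` (donor boundary): an aligned match/mismatch base sits on the last
  exonic nucleotide before the intron. `b` captures intron retention and is
  reported as evidence only; no downstream statistic consumes it. Note `b`
  is not a subset of `s`: a read ending exactly on the donor base carries
  the boundary nucleotide without spanning.

The counting unit is the read (each mate independently). Soft-clipped
bases are excluded from the alignment span. Duplicate handling is
`identical` (one representative per fragment signature) by default, with a
UMI-keyed mode for platforms that provide molecular identifiers.

## Enrichment score

For sample *i* at event *spl* in a run of *n* samples:

```
pc_i   = max(10, 0.01 · s_i)
l_i    = (r_i + pc_i) / (s_i + pc_i)        # pseudocounted usage
l'_i   = r_i / s_i            (0 if s_i=0)  # raw usage
ERS_i  = l'_i / mean_{j≠i}(l_j)
```

The pseudocount floor of 10 reads (rising to 1% of spanning reads at high
coverage) damps sampling noise where coverage is thin. The numerator uses
the *raw* ratio: with pseudocounts alone, absent coverage (r = s = 0)
would give l = 1 and a spuriously enriched score. The denominator keeps
pseudocounts so the background mean is strictly positive. Both choices are
configurable (`numerator_pseudocounts`) for comparison.

Properties worth knowing:

- A neutral event shared equally across samples scores ~1; a run of at
  least 4 equally processed samples is recommended so the leave-one-out
  background is stable (the scorer warns below that).
- The pseudocount does not vanish asymptotically: at usage proportion *p*
  the infinite-depth score is `1.01·p / (p + 0.01)` — 1.000 at p = 1,
  0.990 at p = 0.5, but 0.977 at p = 0.3. Reference junctions (p near 1)
  are unaffected; very minor isoforms are slightly shrunk by design.
- With a single sample the background is undefined and scoring refuses to
  run rather than returning a degenerate value.

## Significance

Overlapping 150 bp reads are not independent trials, and the marginal
information of an extra read falls with depth. Both proportion tests
therefore run on square-root transformed counts — successes `√r_i` out of
trials `√s_i`, used as non-integer values without rounding or continuity
correction (the transform already deflates the counts; a continuity
correction would distort further):

- `p_all`: two-tailed chi-square homogeneity across the k samples of the
  run (samples with s = 0 excluded; undefined with fewer than two usable
  samples).
- `p_sample`: one-tailed pooled two-proportion z-test of sample *i*
  against the pooled rest, `√(Σ_{j≠i} r_j)` out of `√(Σ_{j≠i} s_j)` —
  square roots of the sums, not sums of square roots. Only enrichment
  produces small p; a depleted sample scores ≥ 0.5.

The transform makes the null conservative (empirically far fewer than 1%
of homogeneous junctions fall under p = 0.01), which suits a diagnostic
screen that ranks by ERS and uses p as a guard. `p_all` can reject
homogeneity while no single sample is *enriched* — the signature of a
reference junction depleted in one sample. Raw p-values at the 0.01
working cutoff are the primary output; Benjamini–Hochberg columns are an
optional, clearly separate extension.

## Interpretation layer

- **GAP filter**: events with gap length ≤ 3 nt would imply an intron
  shorter than 4 nt and are artefacts; they are filtered (idempotently)
  before review.
- **Ranking**: per sample, events sort by descending ERS, ties broken by
  descending `r` then coordinates (fully deterministic). Events with
  ERS > 5 carry the review flag; relevant events can sit below 5 when a
  variant spawns several events, a natural event is upregulated, or two
  samples share the effect — those surface through drop linkage instead.
- **Drop detection**: a strong alternative event depresses the reference
  junctions around it. A reference junction is drop-flagged in a sample
  when its ERS < 0.8 *or* is the group minimum (the rule is disjunctive;
  minimum-only drops at ERS ≥ 0.8 are tagged low-confidence rather than
  suppressed). "Close proximity" for linking candidate events to a drop is
  operationalized as overlap with the flanking exons [start of exon k, end
  of exon k+1] — the narrowest window that always contains the junctions a
  local event perturbs.
- **Catalog matching** is exact-coordinate; near misses are real
  differences in splice-site usage, not matches.
- Artefact review (splice-motif plausibility, read-count sanity) remains a
  human step; the emitted evidence columns (r, s, gap length, drop
  linkage, known-event source) are its inputs. Automated motif scoring is
  out of scope.

Classification of events against the transcript model names donor and
acceptor in genomic orientation (donor = lower coordinate), so labels are
strand-invariant; for minus-strand transcripts the biological 5'/3' roles
swap in the wording only. A boundary deviating into an exon is an
alternative donor/acceptor with its Δnt; a boundary deviating into an
intron is a cassette-exon/retention boundary whose partner edge — and
hence frame — is unknowable from one junction. Frame effects are the net
coding-length change mod 3, computed only when both breakpoints relate to
(annotated or assumed) coding exons. Exon numbering is systematic (1..57
for *NF1*); `convert_exon_number` maps to the legacy numbering, which is
+1 for all exons after exon 30.

## Allelic imbalance

Heterozygous SNVs from the DNA call are piled up in the RNA: only aligned
(non-gapped) bases count, so variants under skipped exons lose depth as
expected. Classification bands on the major-allele fraction are
(0.60, 0.70] modest, (0.70, 0.80] intermediate, > 0.80 strong, ≤ 0.60
none — half-open because the published band edges coincide; the bounds are
acknowledged as provisional. At least two informative variants are
required (informative = heterozygous with RNA depth ≥ 20; the depth floor
is this package's addition for fraction stability, configurable).
Variants disagreeing by more than one band make the call not assessable
(phase is unknown; the bands assume the imbalance affects one allele).
Under NMD with degradation fraction *d* of one allele the expected major
fraction is `1/(2−d)`.

## Synthetic runs

The simulator emulates the targeted-panel regime: one transcript model,
150 bp paired reads (fragment 300 ± 50), uniform coverage along the
transcript, 6 samples per run by default, and configurable spanning depth
per junction (default 2000; the study conditions used in tests span
10^3–10^4). ψ is defined as the probability that a *junction-covering
read* carries the alternative event; since shorter isoforms concentrate
more reads over any locus, isoform sampling weights are length-adjusted
(`ψ_i · (L_i − fragment + 1)`) so the realized junction-level fraction
equals ψ irrespective of isoform length. Event grammar terms (`skip`,
`alt_acceptor`, `alt_donor`, `cassette`, `intron_retention`) expand to
isoforms and their expected junctions; explicit junctions are lifted to
isoforms by deleting the gapped segment (with intronic breakpoints
retaining the adjacent intron up to the breakpoint).

What the simulator does *not* model: sequencing-error/quality profiles
(reads are error-free by default; counting keys on CIGAR gaps),
capture-edge coverage falloff, per-junction depth profiles (coverage is
uniform per isoform — platform differences appear only through the global
depth), chimeric reads, and mapping ambiguity. Passing tests therefore
demonstrate the statistical behavior of the scoring and interpretation
machinery under the intended read-count regimes, not robustness to
alignment artefacts — those enter real data upstream of this tool. Two
known edge effects: terminal junctions receive roughly half the configured
depth (mate start windows clip at transcript ends), and junction-level
ψ estimates carry binomial noise plus a small (< 0.5 SE) Jensen bias from
fragment-length variation.

Determinism: one `numpy` generator seeded from the config drives
everything; a fixed seed reproduces byte-identical BAM output.

## Numerical and degenerate-input choices

- Chi-square with p̂ at 0 or 1 (no successes anywhere, or saturated):
  statistic 0, p = 1.
- Two-proportion z with zero pooled variance: p = 0.5 (no evidence in
  either direction).
- `l'` at s = 0 is defined as 0; ERS of an r = 0 event is exactly 0.
- Ties in ranking are broken by descending r, then coordinates, so output
  ordering is reproducible across platforms.
- Sparse count matrices (a sample missing an event's row) are rejected
  rather than silently treated as zero — the dense matrix is the contract
  of the counting stage.

## Problem sizes used in the test suite

The bundled tests and the acceptance script use a compact panel stand-in —
eight 150 bp exons with 300 bp introns — at spanning depths of 10^2–10^4
and 1–100 simulated replicates per property. These sizes were chosen as
the smallest at which the asserted effects (neutral calibration ±0.05,
≥ 95% spike recovery at ψ = 0.2, null calibration at the 1% level) are
comfortably resolvable.

## Known limitations

- ERS compares within one run only; no cross-run background borrowing.
- Intron retention is visible through `b` and depressed `r/s`, but not
  quantified as an event of its own.
- No transcript reconstruction: multi-junction haplotypes of a single
  variant appear as separate events.
- Frame-effect calls ignore premature stop codons introduced by retained
  intronic sequence; cassette boundaries report frame unknown.
- The imbalance bands are the published provisional ones; no
  beta-binomial or phased ASE model is attempted.
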