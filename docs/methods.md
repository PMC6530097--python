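# Methods

## The assay being modelled

RNase H-mediated depletion removes chosen transcripts from total RNA before
library preparation: antisense DNA oligos are hybridized to the target
mRNAs, RNase H digests the RNA strand of each RNA:DNA hybrid, and the
cleaved targets then fail polyA+ selection. The package models the complete
loop around that assay — oligo design, a generative model of the mechanism's
effect on fragment counts, and the statistics used to judge depletion
success — with the bovine milk-protein panel (six genes, twelve oligos, two
concentration schemes) shipped as reference data.

## Oligo design

Candidates are every window of every allowed length (default 24–30 nt) on
the canonical isoform's mRNA. Filters and ranking encode the assay's
constraints:

* **Melting temperature.** Nearest-neighbor DNA/DNA thermodynamics (unified
  Allawi/SantaLucia parameters via Biopython) with the entropic
  monovalent-salt correction; the DNA:RNA hybrid is approximated by its
  DNA/DNA proxy, since the assay's acceptance rule (Tm > 65 °C) was stated
  without hybrid-specific conditions. The default conditions — 250 mM Na⁺,
  250 nM oligo — were fixed once so that all twelve oligos of the validated
  bovine panel clear the 65 °C floor (they span 66.5–74.4 °C under these
  defaults); both conditions are user-overridable.
* **Sequence context.** Windows overlapping annotation masks (repeat /
  low-complexity BED) or scoring above a DUST-style triplet threshold
  (default 2.0), or overlapping any known variant position, are
  disqualified. A window spanning a splice junction is kept only if its
  sense sequence occurs in **every** isoform (isoform coverage 1), because
  an oligo spanning a junction absent from some isoforms leaves those
  isoforms undepleted — the escape mode observed for genes with many splice
  variants.
* **3′ proximity.** Distance to the mRNA 3′ end is a soft objective
  (minimized in ranking), not a hard cutoff: real designs accepted 35–443 nt
  when sequence context forced it. Proximity matters because the fragment
  3′ of the cut still carries the polyA site and survives polyA+ selection;
  the shorter that remnant, the likelier it is lost in cleanup.
* **Ranking** is lexicographic: fewest flags, then maximal isoform
  coverage, then minimal 3′ distance, then Tm closest above the floor; ties
  break by leftmost window then sequence, making selection deterministic.
  The best `n_per_gene` (default 2) pairwise non-overlapping windows are
  selected; a gene with no surviving candidate yields an explicit
  design-failed record, never an exception.
* **Off-target scan**: a sliding-window Hamming comparison of the sense
  window against every other gene's isoforms (default: zero exact off-target
  occurrences). This replaces an interactive BLAST check with a
  self-contained equivalent at transcriptome scale.
* **polyA QC**: target mRNAs are screened for internal A-runs longer than
  7 nt (excluding an annotated terminal tail); such runs act as false polyA
  signals after cleavage and are surfaced as per-gene warnings.

Concentration schemes: A assigns the validated per-gene concentrations
(8.33–25 µM) where gene names match the bovine panel and a user map
otherwise; B is equimolar 25 µM. The variant-A values are shipped as a
literal lookup — they do not map linearly onto any abundance table.

## Depletion simulator

Per molecule of a transcript of length L with bound oligos cutting at
points c₁ < … < c_k (hybrid midpoint, rounded toward 3′) with independent
efficiencies e_i, polyA+ selection keeps the span from the 3′-most realized
cut to the 3′ end. The expectation over the 2^k binding configurations
collapses to a sorted-product closed form (implemented in
`effective_retention` and cross-checked against brute-force enumeration in
the tests). Cleavage remnants shorter than `min_retained_length` (default
150 nt, roughly the insert-size floor of a paired-end library) are lost
entirely; intact molecules are taken as sequenceable by construction, so an
undepleted library reproduces the abundance profile exactly.

Counts are fragment (pair) counts. A library of `library_size` fragments is
drawn multinomially over genes with weight = profile fraction × mean
retention (abundance fractions are defined as fragment shares of the
undepleted library); within a gene, a (isoform, 3′-most-cut) configuration
is drawn per fragment with probability ∝ configuration probability ×
retained length, and the fragment start is uniform on the retained
interval. Per-exon counts assign each fragment to the union exon containing
its start, so per-gene counts equal per-exon sums and column sums equal the
library size exactly. Isoforms in which an oligo's window is interrupted by
splicing are not cut by it, which produces the escape floor. No GC or
positional bias beyond the depletion mechanism is modelled — this is the
smallest model that reproduces the observed artifacts (3′-residual signal,
coverage decline 5′ of the oligo, isoform escape).

The full study generator emits the factorial grid of the validating
experiment: `n_animals` (default 3) × {non-challenged, challenged} ×
treatments {0 = no depletion, A, B}, 18 libraries by default. Animal-level
lognormal jitter (σ = 0.25) on target fractions spreads per-animal target
shares about the template, mimicking inter-individual variability. The
challenged condition scales target-gene weights by
`challenge_target_scale` (default 0.27, chosen so a 61% target share drops
to about 30% after renormalization, the pattern seen in infected tissue)
and applies the ground-truth `de_genes` fold changes; one animal (default
the third) can be assigned a near-total shutdown scale (0.002), the
phenotype of an individual whose target synthesis has effectively ceased.
Treatment efficiencies default to e = 0.85 (variant A) and 0.95 (variant
B): per-oligo efficiency is the free parameter of the model — real data
constrain only net per-gene outcomes — and the defaults encode the
consistent observation that the higher equimolar input of scheme B depletes
more strongly. A single seeded generator drives the whole grid in fixed
order, so runs are reproducible byte-for-byte.

Because the designer places oligos at the extreme 3′ end whenever the
sequence allows (the fixture genes are unconstrained random sequence),
simulated depletion is typically near-complete — stronger than wet-lab
outcomes, where hybridization kinetics, secondary structure and imperfect
oligo placement leave a ~50% residual. The evaluation statistics are
exercised across this whole range by varying efficiencies and placements.

## Evaluation statistics

* **Target fraction**: 100 × target fragments / all assigned fragments per
  sample; the per-gene variant gives each target's own percentage. Group
  summaries average per-animal percentages (not pooled fragments), which is
  the convention that reproduces the published group values; rounding to
  integer percent is presentation-only (half-up).
* **FPKM**: count / (union-exon kb × library millions); the per-exon
  variant uses exon length with the whole-sample library size.
* **Expression quartiles**: per-locus average FPKM over all non-depleted
  samples (both conditions); loci below 1.0 and the targets are removed;
  the 25/50/75 percentiles of the survivors fix four categories, and
  per-category mean FPKM is then computed per treatment pooling conditions.
  Because depleted libraries redistribute the freed fragments, category
  means shift upward after depletion — the sensitivity gain.
* **Detection delta**: genes with FPKM strictly > 1 only after depletion
  (gained) or only before (lost); net = gained − lost. Loci exactly at
  threshold count as not exceeding it.
* **Depth model**: raw = R / ((1−p)·u), reported exact and rounded to the
  nearest million. At p = 0.30 the model gives 42.86 M (= 30/0.7), slightly
  above the informally quoted 42 M for that scenario; the exact value is
  reported.
* **Exon profiles / 3′ bias**: per-exon FPKM plus the ratio of mean FPKM of
  exons 3′ of the 3′-most oligo to mean FPKM of exons 5′ of the 5′-most
  oligo. In depleted samples this ratio exceeds its non-depleted
  counterpart — the polyA-remnant artifact.
* **Correlation**: Pearson r of log₁₀ FPKM between depleted and
  non-depleted samples, per condition, on genes positive in both (no
  pseudocount — an arbitrary ε would distort a headline statistic;
  degenerate cases return NaN rather than raising).
* **DE sensitivity**: per gene, challenged vs control counts pooled across
  animals and tested with a conditional binomial test against the
  library-size split, Benjamini–Hochberg at q < 0.05; power and observed
  FDR are computed against the simulator's ground-truth labels. This is a
  deliberately simple, self-contained test — it shares no dispersion
  machinery with any external DE tool — sufficient to demonstrate the
  mechanism of interest: freeing 60% of the library multiplies the counts
  of every non-target gene ≈ 2.5-fold, which raises power for lowly
  expressed genes at equal sequencing depth.

## Synthetic fixtures and what passing tests show

The fixture generator writes a single-contig genome with six abundant
target genes (named and weighted like the bovine milk-protein panel,
together 61.3% of fragments) over a lognormal background, plus the two
planted failure modes (a multi-isoform target with a skipped exon; a target
with an internal 9-nt A-run), masked repeat/low-complexity intervals and
variants inside and outside plausible oligo windows. Gene structures are
tens of times shorter than real mammalian genes and the sequence is i.i.d.
random: there is no secondary structure, no GC bias, no mappability
problem, no expression noise beyond multinomial sampling. Tests passing on
these fixtures validate the arithmetic, the mechanism model and the
decision logic — not wet-lab transferability of any particular oligo.

Problem sizes were chosen so the whole suite exercises every code path at
comfortable statistical resolution: study simulations use 40–50 genes and
libraries of 10⁵–10⁶ fragments, efficiency recovery averages 10 seeds at
10⁶ fragments, and the DE power comparison averages 20 seeded studies of
12 libraries × 60 000 fragments each.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GTF I/O converts to/from
  1-based inclusive at the boundary. Minus-strand mRNA coordinates run
  5′→3′ (position 0 = cap end), since oligo-to-3′-end distances live in
  mRNA space.
* Cleavage site = hybrid midpoint rounded toward 3′; RNase H cleaves within
  the hybrid and no finer convention is warranted.
* Selection ties break by leftmost mRNA start, then lexicographic sequence.
* `quartile_categories` requires ≥ 4 surviving loci; `target_fraction`
  rejects empty sample columns; `reduction_percent` rejects p₀ = 0;
  `required_depth` rejects p ≥ 1; a gene without designable candidates
  produces a design-failed record.
* The protocol's RNA-integrity side effect (RIN drop of ~2 units) is not
  modelled: it has no established count-level consequence.

## Known limitations

DNA:RNA hybrid thermodynamics are proxied by DNA/DNA parameters; no
secondary-structure (hairpin/dimer) screening; the off-target scan is exact
Hamming matching, not an alignment; per-oligo efficiencies are free
parameters, not fitted to any dataset — calibrating them against observed
per-gene outcomes is left to the user via `efficiency_by_oligo`; the DE
test is a pooled binomial, not a replicate-dispersion model, so its
absolute power values should be read comparatively (between treatments at
equal depth), not as projections for real designs.
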