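# Methods

`auxphase` reimplements, as a tested pipeline over synthetic data, the
computational core of a comparative analysis of auxin response in the two
generations of the plant life cycle (haploid gametophyte vs diploid
sporophyte, both free-living in ferns): promoter AuxRE syntax, transcriptional
response profiling, cross-species orthogroup overlap, and two quantitative
morphometric assays.

## Promoter windows

Promoters are TSS-anchored intervals running from 600 bp upstream of the
transcription start site to the translation start site or 1 kb downstream of
the TSS, whichever is closer.  Internally all coordinates are 0-based
half-open; GFF3 (1-based inclusive) is converted on parse and BED is emitted
0-based.  Sequences are stored in transcript orientation (minus-strand
windows reverse-complemented), so downstream motif offsets are promoter
coordinates regardless of genomic strand.

Decisions where the procedure was genuinely open:

* **Multi-transcript genes** — the transcript with the lexicographically
  smallest ID is used, a deterministic stand-in for "primary transcript".
* **Genes without an annotated CDS** — the downstream cap applies (the gene
  stays analyzable); it is warned about at parse time.
* **TSS = translation start** (no 5′ UTR) — the window is the 600 bp
  upstream stretch only, a literal reading of "to the translation start".
* Ambiguity codes are retained in sequences; motif scanning treats any
  non-ACGT base inside a footprint as a non-match.

## AuxRE hexamer and repeat syntax

The auxin response element is scanned as the 16 `TGTCNN` hexamers (fixed
TGTC core + 2 free bases).  Both strands are scanned — ARF binding sites are
functional in either orientation, and the repeat analysis needs per-copy
strand anyway; a minus-strand hit is reported at its footprint's left edge
with the hexamer written core-first.  Pairs of occurrences with spacer
`right_offset − left_offset − 6` in [0, 25] are classified by orientation:

* **DR** — both copies on the same strand;
* **IR** (inverted, convergent) — left `+`, right `−` (`TGTCNN…NNGACA`);
* **ER** (everted, divergent) — left `−`, right `+` (`NNGACA…NNTGTC`).

The IR/ER naming follows the everted-repeat usage of the ARF literature
(divergent TGTC cores = ER).  The (orientation, spacer) class of a promoter
is invariant under reverse complement (property-tested).  The spacer is
measured between 6-mer footprints, not 4-mer cores, because the hexamer is
the unit of analysis throughout.

Enrichment is a gene-level 2×2 Fisher exact test, one-sided "greater"
(over-representation is the hypothesis): a gene counts as "with" a feature
if it has ≥ 1 occurrence; pair multiplicity is not used.  The one-sided
Fisher p is computed as the hypergeometric upper tail
`P[X ≥ fg_with]`, `X ~ HG(fg_total + bg_total, fg_with + bg_with, fg_total)`
— identical to the Fisher exact one-sided test and verified against
big-integer enumeration to 1e−12 on every table with pooled N ≤ 40.
Reported p-values are raw, matching how −log10(P) heatmaps are usually
drawn; Benjamini–Hochberg q-values are emitted as an auxiliary column.
The background set is "resting genes": every promoter-bearing gene not in
any foreground set, with foreground/background disjointness enforced.

## Response profiles

DEG classification: `up` iff `padj < alpha` and `log2fc > lfc_threshold`
(default α = 0.05, threshold 0; a non-stringent fold-change > 1.25 filter is
expressed as `lfc_threshold = log2(1.25) ≈ 0.32`).  Missing `padj` is `ns`.

Amplitude decomposition ranks one direction's DEGs by |log2fc| and contrasts
the k strongest with the k weakest (default k = 20): per-group means of mock
and treated normalized expression (log2 scale) plus a two-sided rank-sum
test per condition.  "High amplitude from deeper repression" appears as a
lower mock mean at similar treated means.  When fewer than 2k DEGs exist,
k is clamped to the available count and the groups may overlap (flagged
`k_clamped`); the disjointness guarantee holds whenever n ≥ 2k.

The rank-sum test enumerates the exact tie-corrected null for pooled
n ≤ 12 and otherwise uses a normal approximation with continuity and tie
corrections plus an Edgeworth kurtosis term built from the exact tie-free
fourth cumulant `κ₄ = −mn(N+1)(m² + n² + mn + N)/120`.  The correction
keeps the approximate branch within ~0.016 of the exact enumeration at the
crossover size (plain normal + continuity errs by up to ~0.035 there); with
heavy ties at small n no continuous approximation is accurate, which is why
small samples always take the exact branch.

Z-score normalization (for TPM developmental-stage comparisons) is per-gene
with sample SD (n−1); constant genes map to all-zero rather than NaN.

## Orthogroup overlap

Gene or phosphoprotein ids are converted to OrthoFinder-style orthogroups
(first assignment wins on the rare duplicate) and compared as orthogroup
sets.  The enrichment universe is the set of orthogroups represented in
*both* compared species — only jointly representable orthogroups can
overlap.  The test is the exact hypergeometric upper tail; note the
monotonicity this implies: a fixed overlap is *less* surprising in a
smaller universe, so restricting the universe is conservative in the
direction of larger p.  Multi-set (≤ 5) Venn/upset counts use exact set
algebra.

## Morphometrics

Vein indices from per-leaf touch (T), end (E), break (B) and exit (X) point
counts.  The source method's formulas are not public in closed form, so the
package defines operational indices (plug-in replaceable):

* absolute cardinality `T+E+B+X` (how much vein),
* connectivity `T/(T+E+X)` ∈ [0,1] (how often veins meet rather than end),
* continuity `1 − B/(T+E+B+X)` ∈ [0,1] (how uninterrupted strands are),

chosen so that more abundant, better-connected venation raises cardinality
and connectivity.  Relative indices divide by the control-group mean to
allow pooling of experiments.  Group comparison is two-stage: a two-sided
variance-ratio F-test at α = 0.05 selects pooled-variance vs Welch t.

Ploidy quantification: binarize (Otsu by default; fixed threshold by
argument), label connected components at 4-connectivity, discard components
with area < 30 px (sub-nuclear debris), and measure mean intensity of each
surviving ROI on the *original* image.  Groups are summarized by the median
ROI intensity (robust to segmentation outliers); a genome doubling is
expected to double the ratio.

## Synthetic-data generators

The generators produce inputs with the statistical structure the analyses
assume, plus truth tables, and are pure functions of their config: one root
seed expands to per-component child streams via
`SeedSequence(seed, spawn_key=(component,))` with fixed component numbers,
so adding a generator never perturbs existing outputs.

* **Promoters** — 150 foreground vs 1000 background sequences of 600 bp
  (mirroring the upstream window) at GC 0.40; a planted feature (single
  TGTCGG or a (DR,7) TGTCGG repeat) overwrites a uniform position in 40% of
  foreground and 5% of background promoters.  A planted repeat necessarily
  contains two hexamer copies, so one planting enriches both the hexamer
  and the configuration.  Chance motifs in the random background remain and
  are accounted for by rate-0 baselines.
* **DE tables** — 10 000 genes, 2000 responsive, up with probability 0.75
  (activation dominance).  Up genes sit at the generation's mock level
  (defaults 3.78 / 2.76 log2 for the gametophyte- / sporophyte-like
  generation, the reported top-20 levels) and rise to a gene-specific
  induced level (mean 7.0, SD 1.0 log2) *shared between generations*; down
  genes mirror this.  Replicate noise is N(0, 0.25 log2) over 3 replicates
  — typical dispersion for strongly expressed genes, which are the ones the
  top-k decomposition inspects.  Adjusted p-values are emulated (10^−U(3,10)
  for responsive, U(0,1) for null genes); this is a stand-in for a DE
  fitter, not a DE method, and its uniform null admits ~α false positives
  into the DEG set — truth-restricted recovery is therefore the right
  comparison for the planted direction ratio.
* **Orthogroups** — 500 orthogroups with 0–3 genes per species
  (P = 0.1/0.5/0.25/0.15); each species' 50 DEG orthogroups are drawn with
  a fraction `deg_overlap_rate` from a shared jointly-represented core,
  rate 0 reproducing the independence baseline.
* **Veins** — per-leaf counts are independent negative binomial
  (gamma-Poisson) around group means, Poisson at dispersion 0.
* **Nuclei** — 50 non-overlapping discs (radius 6 px) per 400×400 image;
  group-b intensities are group-a × ratio × unit-mean lognormal
  (CV 0.05); background is |N(0, 1%)| of the base intensity.

What the generators do *not* emulate: real promoter composition beyond GC
content (no chromatin, no repeat families), count-level RNA-seq noise or
DE-model shrinkage, orthogroup size biases from gene-family expansion,
optically realistic nuclei (no PSF blur, no overlapping Z-projections).
Passing recovery tests therefore demonstrates correctness of the analysis
machinery under the stated statistical structure, not robustness to every
artifact of real data.

## Problem sizes and numerical choices

Recovery experiments run 100 independent seeds each (syntax recovery,
orthogroup power, nuclei ratio); the exact-test oracle sweeps every 2×2
table with pooled N ≤ 40.  Fisher/hypergeometric p-values are floored at
the smallest positive double to honour p ∈ (0, 1]; enrichment ties are
broken lexicographically by feature for deterministic ordering; histogram
bins are fixed-width 0.25 log2 units over the observed range.

## Known limitations

* The vein indices are this package's operational definitions; numeric
  comparison against other venation studies requires confirming their
  formulas first.
* Nuclear intensities are in arbitrary units; only ratios and orderings are
  meaningful.
* The promoter module trusts the annotation: no TSS inference, no
  transcript reassembly, no handling of overlapping genes beyond the
  per-gene window rule.
* The motif module scans consensus hexamers only — no PWM scoring, no
  de novo discovery.
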