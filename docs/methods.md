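# Methods

## Glycan model and notation

Released, reduced glycans are rooted trees: the reducing-end residue (opened
to an alditol by borohydride reduction) is the root, and every other residue
hangs off its parent through a glycosidic linkage recorded as (child
anomeric position, parent position). Identities are limited to the six
residues that occur in mucin-type O-glycans and the common GSL series
(Gal, Glc, GalNAc, GlcNAc, Fuc, Neu5Ac); absolute configuration (D/L) and
ring form are not modelled, and sulfation/O-acetylation are out of scope.
O-glycan context requires a GalNAc-ol root (β-elimination products); GSL
context requires Glc-ol or Gal-ol (endoglycoceramidase products).

The text dialect is condensed-IUPAC-like, chosen over GlycoCT/WURCS so that
the names used in glycomics supplementary tables ("Galβ1-3GalNAc-ol") parse
directly. Serialisation is canonical: children of a node are ordered by
descending parent position, unknown positions last, ties broken by residue
name and then by full subtree text (a total order — residue name alone
cannot distinguish two unknown-position children of the same identity); the
lowest-position child continues the backbone and the others are
parenthesised, so the core 2 branch serialises as
`Galβ1-3(GlcNAcβ1-6)GalNAc-ol`. Unknown anomers/positions are stored
explicitly and never guessed.

Masses are monoisotopic, built from atomic masses (Hex 162.05282,
HexNAc 203.07937, dHex 146.05791, Neu5Ac 291.09542; water 18.01056;
reduction +2.01565; proton 1.00728). Composition matching enumerates all
class counts within bounds and keeps those within an absolute Da tolerance
of the query, sorted by error; the default tolerance in examples is ±0.2 Da,
reflecting ion-trap mass accuracy, not a ppm criterion.

## Epitope counting

A motif is a small glycan-shaped pattern. `count_motif` counts the distinct
target residues that can serve as the image of the pattern root under an
injective, edge-preserving mapping that respects identities, anomeric
configurations and linkage positions. Counting distinct root images (rather
than distinct mappings) prevents double counting when a symmetric pattern
embeds in several ways rooted at the same residue. Three rules matter in
practice:

- **Wildcards are one-sided.** A `?` in the motif matches anything; an
  explicit motif value never matches an unknown target value. Structures
  with unresolved linkages therefore contribute 0 to linkage-specific traits
  instead of being guessed into them.
- **Terminal constraints.** When a trait is defined on terminal epitopes
  (Lewis X, sLe^A, blood groups, terminal HexNAc), childless pattern
  residues must map onto leaves of the target.
- **The alditol is special.** The reducing-end GalNAc-ol is excluded from
  "terminal GalNAc/GlcNAc" (otherwise every O-glycan would count once), but
  it *is* a valid acceptor for α2,6-sialylation — the `allow_alditol` flag
  per trait handles both cases. sTn additionally requires position 3 of the
  root to be unoccupied (forbidden-substituent constraint), so extended
  sialylated cores are not miscounted.

Identity wildcards are not implemented: no built-in trait needs one.

O-glycan cores are classified from the root substituents (none → Tn; only
Neu5Acα2-6 → sTn; Galβ1-3 with position 6 empty or sialylated → core 1;
Galβ1-3 + GlcNAcβ1-6 → core 2; GlcNAcβ1-3 alone → core 3; two GlcNAc → core
4; anything else → other). GSL series are decided by the residue extending
the lactose-core Gal: Galα1-4 → globo, GlcNAcβ1-3 → (neo)lacto regardless of
later capping, Neu5Ac and/or GalNAcβ1-4 without a GlcNAc extension →
ganglio, a bare core → core_only, everything else (including
galactosylceramide-type Gal-ol roots) → other. Series membership follows the
core backbone, not terminal decoration, because the three published classes
sum to ~100% per sample — they form a partition. The built-in library adds
`core_only`/`other` catch-alls so the partition is exhaustive by
construction.

The trait library ships as a TSV (name, scope, mode, motif notation or
classifier rule, anchor, terminal/forbidden annotations, alditol flag) and
can be replaced via `--traits PATH`.

In-silico α2-3 neuraminidase digestion removes terminal Neu5Ac attached at
position 3, iterating to a fixed point; it mirrors the wet-lab
annotation-confirmation digest, after which the α2,3-sialylation trait must
read zero.

## Quantification

Relative abundance is 100 × area / Σ areas within each (sample, replicate);
it is scale-invariant per replicate by construction. The 95% coverage rule
ranks glycans by replicate-mean abundance per sample and keeps the minimal
prefix reaching 95% — applied on sample-level means so the glycan set is
identical across replicates (the source protocol does not specify
per-replicate vs per-sample; per-sample keeps replicate SDs meaningful).
Values are **not** renormalised after filtering: traits remain percentages
of the original total, so dropping the ≤5% tail biases any trait downward
by at most 5 points (and class-partition sums land between 95 and 100
instead of at 100). Trait values are Σ_g rel(g) × count(g, trait); with
epitope multiplicities > 1 they can exceed 100% and are not clamped.
Replicate aggregation uses the sample SD (n−1; SD = 0 when n = 1).

## Expression screen

The preprocessing chain is RMA-flavoured but deliberately simplified where
bit-exact replication of array pipelines is not the goal:

- **Background**: per array, subtract the 2%-quantile and clip at a small
  positive floor. This replaces the exon-model convolution background; it is
  monotone within each array.
- **Quantile normalisation**: each entry becomes the across-array mean of
  the values at its within-array rank; ties receive the mean of their
  rank-values. Afterwards all arrays share identical sorted values exactly.
- **Summarisation**: Tukey median polish per probe set on log2 intensities
  (alternate row/column median sweeps; tolerance 1e-6, up to 50 sweeps — 10
  sweeps are not always enough to drive residual row/column medians below
  1e-6). Gene expression per array = overall effect + column effect.

The per-gene two-group fit is a moderated t: pooled variance s² with
d = n1+n2−2 df, shrunk to s̃² = (d0·s0² + d·s²)/(d0+d) with the prior
(d0, s0²) estimated by the method of moments on log s² across genes
(trigamma-inverse of the excess spread of log s²; when the spread does not
exceed chi-square sampling noise, d0 = ∞ and s0² is the mean sample
variance). The reference distribution is t with d0+d df, capped at the
pooled residual df over all genes. With `prior="none"` the fit reduces
exactly to the classical pooled two-sample t. The implementation is
cross-checked against an independent Bioconductor limma run in the test
suite; limma is never used by the package itself.

P-values are Benjamini–Hochberg adjusted (via statsmodels, verified against
the hand-applied step-up formula). A gene passes with |FC| ≥ 1.5 on the
linear scale and adjusted p < 0.1 — the defaults; both thresholds are
configuration because the source analyses quote both an adjusted-p rule and
a stricter raw-P rule, and the package reconciles neither silently.
Passing genes are rolled up into functional categories (unmapped →
"miscellaneous"; percentages rounded to integers for the report) and
exported in average-linkage (1 − Pearson) leaf order for heatmap viewers,
with rows pre-sorted by gene name so the order is deterministic.

## Synthetic data: what it emulates, and what it does not

The reference panel holds 40 named structures (22 O-glycans, 18 GSL
glycans) spanning every library trait; stored epitope counts are recomputed
from the motif engine at panel build time, never hard-coded. The sTn and T
antigens and the bare lactose core are definitionally single structures, so
those traits are carried by exactly one panel member; every motif-counted
trait has at least two carriers.

Peak tables: per replicate, area = profile fraction × sample total ×
LogNormal(mean 1, CV). Multiplicative log-normal noise reflects that MS peak
areas are positive and right-skewed. Defaults emulate the study design: two
samples (an epithelial-like profile rich in core 2, fucosylated and
2,6-sialylated species and (neo)lacto GSLs; a mesenchymal-like profile with
globosides, gangliosides and α2,6-sialylated GalNAc), N = 3 replicates,
CV 5%. Planted profiles are specified at the *glycan* level and pushed
through the epitope-weighted formula to obtain planted trait values, so the
trait formula itself is under test, not assumed. Under these conditions the
zero-noise limit recovers planted traits exactly, and at CV 5% about 99.9%
of recovered trait means fall within 1 percentage point of the planted
values (the quoted ≥95% calibration is a statement about recovered means,
not about the maximum error across the whole trait panel in a run).

Probe matrices: log2 intensity = gene baseline (N(8, 1.5²)) + planted group
effect (±1 log2 unit for 10% of genes) + probe affinity (N(0, 0.5²)) +
N(0, 0.2²) noise, exponentiated to the intensity scale; 3 probes per gene,
1,171 genes, 3 arrays per group — the scale of a custom glyco-gene array.

What the generators do **not** emulate: isomer co-elution and shared
compositions, in-source decay, missing peaks, retention-time drift,
probe-sequence effects, spatial array artifacts, or correlated noise across
replicates. Passing tests therefore certify the arithmetic of the pipeline
under the stated noise model, not robustness to those real-data phenomena.
One consequence worth noting: with zero noise the planted group shifts
themselves make array distributions differ, so quantile normalisation is
not FC-preserving in that limit; the exact-recovery guarantee applies to the
summarisation + fit path.

## Numerical choices and degenerate inputs

- Seeds: every generator takes an explicit seed; fixed seed ⇒ bit-identical
  output. The acceptance script derives all stream seeds from `--seed`.
- Coverage filter bound uses a 1e-12 slack on the cumulative sum so that an
  exact 95.0 boundary keeps the prefix that reaches it.
- Median polish on a 1-row or 1-column block degenerates correctly (the
  median of one value is itself); a single probe per gene passes its log2
  values through unchanged.
- An all-constant gene has s² = 0: rejected with `prior="none"`, shrunk to
  the prior with `prior="moments"`.
- Glycans present in a peak table but absent from the epitope table
  contribute zero to every trait and trigger a warning, not an error.
- Null type-I calibration of the moderated test is assessed as the mean
  rejection fraction over independent simulations: the shared variance
  prior correlates p-values within one run, so a single-run fraction has
  much more spread than binomial.

## Known limitations

- No MS/MS fragment interpretation or retention modelling: structures are
  taken as annotated.
- The notation covers the six-residue alphabet only; no GlycoCT/WURCS
  import/export.
- The screen does not parse CEL files and does not reproduce any specific
  published gene list; its behaviour is certified on synthetic matrices
  with planted truth.
- Trait definitions for sialylation/fucosylation count every motif
  occurrence, including internal ones; published panel definitions may have
  counted terminal epitopes only — with the library TSV both conventions
  can be expressed.
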