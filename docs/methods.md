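# Methods

## Differential expression

Counts are normalized with median-of-ratios size factors (per-gene
geometric-mean reference over all samples; only genes with nonzero counts
in every sample contribute; factors rescaled to geometric mean 1). When no
gene is expressed in all samples the code falls back to total-count
scaling and records a warning; wholly empty libraries keep factor 1.

The DE test is a negative-binomial Wald test on normalized group means
with variance Var(X) = μ + αμ². Per gene, the delta method gives
Var(log2 m̂) ≈ (μ + αμ²)/(n μ² ln²2), the Wald statistic is
log2FC / SE and the p-value is two-sided normal. There is no dispersion
shrinkage and no fold-change shrinkage: the engine is deliberately simple
and fully oracle-testable, because the scientific content of the chain is
the calling rule and the downstream classification, not the DE machinery.
A cross-check test confirms rank agreement of p-values (Spearman ρ > 0.85)
and log2FC correlation (r > 0.95) with an independent DESeq2-style fit on
the same simulated data.

Dispersion `alpha_mode`:

* `shared_mom` (default) — one α shared across genes, estimated by the
  pooled ratio of sums Σ(s²−m)/Σm² over genes and groups. The more obvious
  median of per-gene moment estimates is biased low at n = 3 (its null
  type-I error was ≈ 0.08 rather than 0.05 in calibration runs), while the
  ratio-of-sums estimator recovers the generating α to within a few
  percent and keeps the null type-I error inside [0.03, 0.07].
* `per_gene_mom` — per-gene moment estimates (anticonservative at small n;
  provided for sensitivity analyses).
* a fixed numeric α.

Degenerate inputs: genes all-zero in both groups get p = 1 and log2FC = 0;
when exactly one side is all-zero, a pseudo-mean floor of 0.5 normalized
counts enters the log (and the variance) so fold changes stay finite.
Dispersion estimates are floored at 1e-8.

Calling rule: up iff log2FC > log2(2) and BH-FDR < 0.05, down symmetric.
The fold-change gate applies to the point estimate. BH correction is
applied within each test family (one contrast, or one comparison over the
type-V genes of a trio × condition); a global scheme would be stricter but
does not match per-contrast DE convention.

FPKM is counts·10⁹/(length·N) with union-exon gene lengths from GTF
(1-based closed intervals converted to 0-based half-open before the
interval-union sweep) and N either the raw library total or the
size-factor-based effective total. Replicate QC is Pearson correlation on
log2(x+1), the variance-stabilized scale conventionally used for
sample-level QC.

## Inheritance classification

"Expressed" is value ≥ τ in ≥ k replicates (defaults τ = 1, k = 2, on FPKM
when gene lengths are available, otherwise on normalized counts).
Exact-zero rules are fragile under sampling noise; the threshold rule is
the operational replacement and both parameters are exposed.

PAV types I–V follow the standard truth table over the three expressed
flags; genes silent in all three cells are reported as `not_detected`,
never dropped silently. Within type V, four NB Wald comparisons are run —
F1 vs P1, F1 vs P2, F1 vs a mid-parent pseudo-group, and P1 vs P2 — each
BH-corrected across the type-V genes of that trio × condition. The
mid-parent pseudo-group pairs parental replicates by replicate index and
averages each pair, so it respects replicate variance; its NB variance
model overstates the pseudo-group variance slightly (the mean of two NB
variables is less dispersed than one NB variable at the same mean), which
errs on the conservative side for the additive call.

"Equal" means not significant under the same |FC| > 2, FDR < 5% rule used
everywhere else; the mode rules are then applied with fixed precedence:
additive (F1 = MPV) first, then overdominant (above both parents),
underdominant (below both), high dominance (equal to the higher parent,
parents differing), low dominance; anything left — e.g. partial dominance,
strictly between the parents but off the mid-parent value — is `other`,
because the named taxonomy is not logically exhaustive. Type III genes are
merged with the type-V overdominant class (`merged_overdominant`); the two
inputs are disjoint by construction.

A structural consequence of the 2-fold equality gate worth knowing: with a
4-fold parental split, F1 equal to the high parent is only 1.6× the
mid-parent value, inside the gate, so most true high-dominance genes are
called additive. This is a property of the calling rule itself, not of the
implementation; low dominance (0.4× MPV) is outside the gate and is
recovered. The package therefore treats additive, overdominant and
underdominant as the classes with guaranteed recovery.

## Set algebra

Every derived set records provenance (operation + parent set names) and
`ResponseSets.audit()` re-derives each derived set and compares — run
automatically at the end of the pipeline. Conserved sets intersect
matching directions by default (up∩up, down∩down), with a
direction-agnostic flag for plain ID intersection. Reset accounting
partitions each conserved drought direction set into reset (opposite
call after re-watering) and persistent; fractions are relative to the
drought set size and NaN when that set is empty.

## Heterosis indices

MPH and HPH are computed from replicate means in percent. For all-positive
means HP ≥ MP implies MPH ≥ HPH (asserted on every result), and both
indices are scale-invariant. Significance uses Welch t-tests — the hybrid
replicates against per-replicate parent-pair means for MP, and against the
higher parent's replicates for HP. Welch is the safe default where a plain
Student test was historically used; with replicated, roughly equal-variance
trait data the two agree closely. Duncan's multiple-comparison procedure
is not offered; BH-adjusted pairwise Welch tests have better error
control. Missing phenotype replicates are rejected, not imputed.

## Enrichment

One-sided hypergeometric over-representation (upper tail P[X ≥ k]) with BH
correction, against a user-supplied GMT annotation. The universe defaults
to the detected genes of the analysis rather than the whole annotation —
the defensible background when the query derives from the same detection
step — and can be overridden. Only over-representation is tested.

## The synthetic-data generator

The generator emulates the two-trio design: AB = AA×BB and CD = CC×DD,
three conditions (WW, WD, RW), three replicates — 54 libraries. Counts are
NB(s·μ, α) via the gamma–Poisson mixture, with s a mild lognormal
library-size factor (CV 0.1 by default) and a shared α = 0.05, typical of
replicated plant RNA-seq. One shared seed drives a counter-based substream
per gene, so matrices are reproducible independently of gene order.

Per gene, a baseline log2-mean is drawn uniformly from (6, 11) — expected
normalized counts of 64–2048, the range where the classifiers actually
operate — and a mode is assigned from the default proportions
(additive 0.45, high/low dominance 0.12 each, over/underdominance 0.08
each, PAV I–IV 0.15 total). Hybrid means follow the construction rules
exactly (additive = mid-parent; dominance = one parent with a 4-fold
parental split; overdominant = 4× above the high parent; underdominant =
4× below the low parent; PAV cells have true mean 0, so "silent" really is
zero — an optional stress mode puts silent cells at 0.1× baseline
instead). Parents are split only for the dominance modes, where unequal
parents are definitional; for additive and over/underdominant genes the
parents are equal. This matters: if every gene were parent-DE the
median-of-ratios assumption (a non-DE majority) would fail and size
factors would absorb genuine biology — an early all-modes-split variant
showed exactly that failure.

Condition response: 15% of genes up under WD, 15% down (all roles scaled
equally, ×4 or ÷4), 70% null; responding genes revert to the WW mean after
re-watering with probability 0.6, else stay at the WD level. Modes are
shared across trios by default (the analysis looks for conserved dominance
classes; a flag draws them independently). Phenotype replicates are
zero-truncated normal draws around the specified genotype × condition
means; annotation maps can pack a known fraction of terms with genes of
one mode/response class, with the class recorded in the term name, so
enrichment recovery is checkable.

What the generator does not emulate: GC/length biases, batch effects,
correlated genes, per-gene dispersion trends, allele-specific expression,
and realistic effect-size distributions (all effects are a single
magnitude). Passing recovery tests therefore demonstrates that the
inference chain is correct under its own model assumptions at realistic
depth and replication — not that it would achieve the same sensitivity on
field data, where effect sizes are continuous and many true effects sit
inside the fold-change gate.

## Evaluation choices and problem sizes

Recovery is scored at the WW condition: the response multiplies all roles
of a gene equally, so mode relations are preserved under WD/RW, but
strongly down-responding genes can drop below the detection threshold
there; WW is where the baseline mode construction is defined. Standard
evaluation runs use 2000 genes × 54 libraries for recovery, 5000 genes ×
(3 vs 3) for the null calibration of the DE test, and 150–200 terms for
enrichment calibration — sizes at which sampling error on the reported
rates is ≈ 1% while a full run takes seconds.

## Known limitations

* The Wald/plug-in test is approximate at n = 2–3; `shared_mom` is
  calibrated by construction on the generator's model, but per-gene
  dispersion variation in real data would make it anticonservative.
* High/low dominance calls depend strongly on the ratio between the
  parental split and the fold-change gate (see above).
* Gene identity is the bare ID string; no cross-genome ID mapping is
  attempted (appropriate when all genotypes are mapped to one reference).
* The enrichment module is plain ORA: no ontology topology, no
  gene-length or expression-level bias correction.
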