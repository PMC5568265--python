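# Methods

This note documents the models and numerical choices behind
`hybridhic`, what the synthetic generator does and does not emulate,
and where design decisions were genuinely open.

## Contact-matrix model and balancing

A cis contact map at resolution *r* is stored upper-triangular sparse
over genome-tiling bins (0-based, half-open; bin index = ⌊pos/r⌋; bin
distance = |i−j|·r). Observed counts are modelled as
E[c_ij] = b_i · b_j · T_ij with multiplicative per-bin visibility
biases b and a true interaction matrix T. Iterative correction (ICE)
estimates b by repeatedly dividing rows/columns by their marginals so
every unmasked bin ends with equal visibility.

Numerical choices:

- **Stopping rule.** Convergence is declared when the maximum absolute
  relative change of the bias vector between consecutive iterations
  drops below `eps` (default 1e-4). Bias-change and matrix-change
  criteria agree up to constants; the bias change is cheaper. On
  convergence the coefficient of variation of unmasked marginals within
  a normalization unit is well below 10·eps.
- **Damping.** The per-iteration correction uses the square root of the
  normalized marginal. An undamped update oscillates with period 2
  between the chromosomes of a cis-only map under genome-wide
  normalization (the map is block-diagonal, so cross-block equalization
  has no gradient through shared entries); square-root damping removes
  the oscillation and leaves the fixed point unchanged.
- **Units.** Coarse maps (≥ 20 kb) normalize genome-wide; fine maps
  per chromosome. Both are explicit options (`unit=`).
- **Masking.** Zero-marginal bins are always excluded; bins below the
  1% quantile of nonzero marginals and bins inside assembly-gap
  ("masked") layout segments are excluded too. The 1% quantile is a
  package decision — no threshold is standard — and is configurable.
- **Gauge.** The returned bias vector has geometric mean 1 over
  unmasked bins per unit, so the balanced matrix is defined up to one
  documented global scalar per unit.

Reference-lag scaling divides every entry by the mean unmasked entry at
a chosen lag (default 1 bin: 5 kb on fine maps, 20 kb on coarse maps),
making the mean at that lag exactly 1. This removes sequencing-depth
differences before any cross-map comparison and is idempotent.

## Compactness and decay exponents

Compactness of a 5-kb bin is K_i = Σ value(i, j) over 2 ≤ |i−j| ≤ 10
(10–50 kb, both directions, up to 18 entries) on the balanced,
lag-1-scaled map. K is defined only where at least 80% of the 18
candidate entries exist in-chromosome with both bins unmasked; edge
bins therefore usually carry no value. The 80% rule is a package
decision (the source protocol does not state how partial
neighbourhoods were handled); it trades a small loss of coverage for
comparability of K across bins. On an exact c(d) = (d/5 kb)^−1 map the
interior value is 2·Σ_{k=2..10} 1/k ≈ 3.8580; on a constant map it
is 18.

Decay exponents are computed per non-overlapping, left-aligned 100-kb
window (trailing partial windows dropped): the mean unmasked entry at
each lag 1..10 inside the window, then a least-squares line of
log(mean) vs log(distance). Natural logs; the slope is base-invariant.
Windows keeping fewer than six lag means carry no value. Lag means that
are exactly zero (possible in shallow simulated maps, never in deep
data) are dropped like missing lags, since their log is undefined.

Compactness-ratio quantile classes (default top/bottom 10%) break ties
by genomic coordinate (stable sort) so the sets are reproducible. In
the pipeline's expression integration the ranking is restricted to the
subgenome under study; genome-wide ranking would be dominated by the
between-subgenome compaction offset itself.

## Methylation

Ratios are pooled counts — Σ methylated / Σ sequenced cytosines of the
context in the interval — never means of per-site ratios, so a union of
intervals equals the count-weighted combination of its parts. A bin
with no covered in-context site is undefined (NaN), as are bins inside
masked layout segments. Cutoff grouping sends values exactly at the
cutoff to the low group (documented, configurable by choosing the
cutoff). Metagene profiles rescale each gene body to 60 positions
(a package choice; only TSS/TTS alignment is prescribed) with flanks in
absolute 100-bp windows, reversing minus-strand genes.

## H3K27me3

"Normalized coverage" is interpreted as counts-per-million scaling of
each library over its own total (per-genome-mean scaling available);
the H3K27me3/H3 ratio is undefined where the scaled H3 signal is zero
(no pseudocount by default). A gene is marked when its body overlap
with the merged peak union strictly exceeds half its length; exactly
half is unmarked. The threshold-and-merge peak caller shipped here is
plumbing for synthetic ratio tracks only, not a statistical caller.

## Expression statistics

Per-gene log2 fold change and FDR are consumed as inputs; the
count-level DE model that produces them is out of scope. The
fold-change wording in the source protocol ("fold change of log2 fold
greater than 2") is ambiguous between |log2FC| > 2 and fold change > 2;
`min_abs_log2fc` is therefore a required explicit parameter with no
silent default in the pipeline (the demo config uses 1.0, the fold > 2
reading, which suits the generator's moderate effect sizes).

Rank tests delegate to the Wilcoxon–Mann–Whitney implementation with
exact enumeration for tie-free groups of ≤ 20 and the normal
approximation with continuity correction and midrank ties otherwise.
The variance contrast reports sample variances of log2(hybrid/parent),
their ratio, and a one-sided label-permutation p-value (seeded,
1000 permutations) for inflation in the marked set.

## FISH volumetry

Voxels strictly above the intensity threshold (default 25) count as
signal; the total volume is the per-slice area sum times the slice
thickness (default 0.22 μm), exactly the classic area-sum estimator
and independent of any connectivity choice. Clusters are additionally
labelled with 26-connectivity in 3D for per-cluster volumes and counts;
inclusion filtering (e.g. requiring two distinct clusters per nucleus)
is left to the caller.

## Synthetic generator: what it emulates and what it does not

The stated world: a hybrid reference of 5 subgenome-A plus 8
subgenome-B chromosomes (numbered 6–13), centred pericentromeres with
masked centromere cores, a fivefold B/A arm TE-density ratio, cis
contacts drawn from E[c_ij] ∝ b_i b_j (d/r)^α with arm α = −1.0 and
pericentromere α = −0.6 (heterochromatin decays more shallowly, i.e.
is more compact), lognormal biases (σ = 0.25), beta-binomial
methylation around context means (CG 0.24, CHG 0.10, CHH 0.04) plus
TE coupling (strongest for CHH, 0.4), ~200 genes/Mb with 22% H3K27me3
marking and 85% parent→hybrid mark concordance, and a −0.5 log2 mean
shift with 0.4 extra log2-ratio SD on subgenome-A genes marked in both
genotypes. Chromosome lengths default to 1.5 Mb — about 1/20 of the
real genomes — so full pipelines run in minutes; all sizes scale up by
configuration.

Exactly `n_pairs` contacts are drawn (a multinomial split over bin-pair
cells: Poisson-like at depth while conserving the total). Trans
contacts default to zero, matching an analysis scope that excludes
mapping-error-prone inter-subgenome signal. All draws flow from one
seeded generator; a seed is required and identical parameters plus seed
reproduce outputs byte for byte.

Not emulated: polymer-physics contact structure (TADs, loops,
compartments), read-level sequences and mapping artefacts, realistic
gene/TE architecture, replicate structure, and the count-level DE
model (the generator's FDR comes from a simple two-sided normal test of
the hybrid fraction of pooled counts, BH-adjusted — plumbing, not a
DESeq2 substitute). A green end-to-end test therefore establishes that
the estimators recover known parameters under the stated noise model,
not that they are robust to alignment or library artefacts.

## Known limitations

- Balancing assumes a connected contact graph per normalization unit;
  all-masked chromosomes are skipped with a warning.
- The decay-exponent fit weights all lag means equally; no
  heteroscedasticity correction is applied (matching the plain linear
  regression it reproduces).
- ICE bias estimates on a linear power-law map absorb genuine edge
  effects (a finite power-law matrix is not exactly balanceable), so
  bias-recovery comparisons are meaningful only against balanceable
  cores.
- `aggregate_region_interactions` enumerates bin pairs in Python; it is
  intended for region sets of tens of bins (KEE/IHI-scale), not
  genome-wide scans.
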