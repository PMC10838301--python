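# Methods

## Codon-set deduction

A tRNA's codon repertoire is deduced from its anticodon written 5′→3′
(positions 34–36). Codon positions 1 and 2 are the Watson–Crick complements
of anticodon positions 36 and 35; codon position 3 is expanded by the wobble
pairing of position 34: inosine (or A read as inosine) pairs {U, C, A};
G pairs {U, C}; U pairs {A, G}; C pairs {G}; unmodified A pairs {U}. Under
the two-out-of-three rule, pairing at the first two codon positions suffices
and position 3 expands to all four bases. Exclusions are applied after
expansion and kept on record with a reason string, so every emitted set
carries its own provenance (`CodonSet.to_manifest()`).

The cytosolic default set {CAA, CAG, CGU, CGC} is the wobble union of
Arg-ICG and Gln-UUG with CGA excluded: reporter data show CGA decoding is
unaffected by m²A loss, consistent with decoding by a different arginine
isoacceptor. The chloroplast set is deduced from the four modified
chloroplast tRNAs (Arg-ICG, His-GUG, elongator Met-CAU, Ser-GGA); because
the exact published set is not pinned by the main text, both the wobble
(8 codons) and two-out-of-three (16 codons) outputs are exposed and the
caller chooses — the package does not guess a single canonical set.

## Tandem scanning and grouping

Scanning is strictly in the annotated frame from base 1; codon indices are
1-based; out-of-frame occurrences are ignored. DNA input is accepted and
normalized T→U because reporter inserts are cloned as DNA. The maximum
tandem run is the longest stretch of consecutive in-frame codons all in the
set (0 if none). Codon frequency is set codons over total codons, excluding
a terminal stop from the denominator by default (configurable) since stops
are not decoded by elongator tRNAs.

Tandem bins default to others (< 3), 3, 4, ≥ 5; bin edges are configurable.
The frequency decile flag uses the empirical quantile (default 0.90) over
the supplied population with boundary ties counted as high — inclusive
ranking is reproducible and order-independent. Groups: A = no tandem/low,
B = tandem/low, C = no tandem/high, D = tandem/high; the partition is
exhaustive and exclusive by construction.

## Translation efficiency and the SNR filter

Per replicate, TE = footprint FPKM over input FPKM for the same gene, with
the footprint table understood as CDS-restricted (the pipeline consumes
precomputed FPKM tables; the restriction reading of "adjusted by reads
abundance on CDS" is implemented and flagged here as an assumption). The
condition TE is the geometric mean over replicates, which commutes with the
per-replicate ratio for two replicates — a property the tests assert. A gene
is "translated" only when input and footprint values exceed their thresholds
(default: strictly positive) in every replicate; other genes are excluded
from group tests rather than imputed.

DE calls require all three of: mean-FPKM fold change beyond 2× in either
direction, BH-adjusted p < 0.05, and SNR > 1 where
SNR = |X−Y| / (|x₁−x₂| + |y₁−y₂|). The zero-denominator convention (SNR = ∞
when the means differ with perfectly reproducible replicates, 0 otherwise)
keeps the filter monotone in replicate consistency. The p-value test is not
dictated by the quantities above; the default is a two-sided Welch t-test on
log2(FPKM + 1) (pseudocount configurable), swappable via the `test`
argument. Zero-variance rows get p = 1: identical numbers cannot be evidence
of change.

Group comparison uses scipy's Kruskal–Wallis omnibus plus pairwise
two-sided Mann–Whitney tests with BH adjustment; "paired comparison" names
no specific procedure, so the rank-sum default is documented rather than
implicit. The compact-letter display uses the insertion–absorption
algorithm; groups sharing no letter differ at adjusted p < α. Degenerate
inputs (all values identical) are reported with a flag instead of a test
statistic.

## Malc

Coordinates are 1-based inclusive spans on the target RNA 5′→3′. The probe
trio shares its 5′ end (covering the target up to boundary E, default
E = X + 8, a ~9-nt protected 3′ flank; the assay's actual probe lengths are
experiment-specific and therefore user inputs) and steps back one nucleotide
at the 3′ end, giving nested protected fragments. Localization is a pure
function of the detection pattern: signal must be monotone along the nested
chain, and any inner-without-outer signal is flagged physically
inconsistent. A fragment counts as detected when its measured ratio exceeds
a configurable limit of detection (default 10⁻³), standing in for the
instrument's qualitative presence/absence.

Quantification inverts the mole ratio: a fragment with modified fraction f
at X contributes f moles of modified nucleoside and A − f of adenosine per
molecule, so R = f/(A − f) and R_m = A·R/(1 + R). The count A includes
position X itself (it reports as A when unmodified) and excludes positions
that never report as A, such as the stoichiometric m¹A58 of cytosolic tRNA
(supplied per target). Noise can push R above the algebraic bound, so
R_m > 1 is clipped to 1 with a warning rather than rejected; R = ∞ (the
fully modified single-adenosine edge) maps to R_m = A before clipping. The
quantification fragment defaults to F(X−1) and is overridable to F(X−2) or
F(X−3) for targets whose shorter fragments have A/U-rich ends, where
residual double-strand nuclease activity trims the fragment and biases the
ratio low — the simulation reproduces exactly this bias via an `end_bias`
factor on F(X).

## Assay reducers

Dual-luciferase: per transfection, activity is firefly/Renilla; within each
genotype it is divided by the mean activity of the empty control construct,
making outputs invariant to any per-genotype rescaling of raw readings.
Replicates are normalized individually and summarized as mean ± SD — no
pooling before normalization. Apparent TE is relative protein over relative
mRNA, with the ratio taken before any cross-genotype normalization.

Melting transitions: the fluorescence trace is low-pass filtered by zeroing
all but the lowest 10% (configurable) of rFFT components; the
endpoint-connecting linear trend is removed before filtering and restored
after, so the implicit periodic extension has no jump and the filter cannot
ring at the grid edges. Transitions are maxima of −dF/dT (central
differences on the possibly non-uniform grid); peaks are ranked by
prominence with a floor of 5% of the derivative range to suppress ripple,
and at most `max_peaks` (default 2) are reported ascending in temperature
(Tm1 ≤ Tm2). Flat or strictly linear curves return no transitions.

## Synthetic data

The generators emulate the statistical structure of the consumed inputs,
not their full biology. Gene population: lengths uniform in 150–450 codons,
AUG start, single terminal stop, no internal stops; per-gene set-codon
proportion uniform in 0.02–0.25 to spread codon frequencies; designed
tandem runs implanted at random in-frame positions with non-set guard
codons at both flanks; background sampling caps spontaneous set-codon runs
at 2 (seeding the counter with the AUG start when it belongs to the set),
so realized max runs equal designed runs. Defaults: 1000 genes, 700/100/100/
100 across others/run3/run4/run6.

Expression: baseline log10 FPKM ~ Normal(1, 0.5); wild-type TE log10 ~
Normal(0, 0.15); mutant TE = wild-type TE × δ(bin); input and footprint
FPKM are baseline (× TE) times log-normal noise with median 1 and CV 0.2.
Because the noise has median 1, the median observed TE fold change of a bin
equals its δ, which is what the recovery tests assert. Two replicates per
condition, matching the consumed design. A negative-binomial count-level
mode (dispersion 0.05, library size 2×10⁷, FPKM back-conversion) exists for
robustness checks.

Malc measurements: true ratio f/(A − f) for fragments containing X, zero
otherwise; log-normal multiplicative noise (default CV 5%, 3 replicates);
optional end-bias factor on F(X) only.

What these simulations do not model: read-level artifacts (alignment,
P-site offsets, footprint periodicity), codon-usage realism beyond the
set/non-set proportion, correlated replicate noise, chromatographic peak
shapes, or partial-digestion patterns beyond the single end-bias factor.
Passing recovery tests therefore demonstrates correctness of the
computations under the stated noise model, not robustness to every artifact
of real libraries.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is a pure function of
(config, seed); pipeline outputs are byte-identical across runs with the
same configuration. The recovery analyses run at 300 genes per tandem bin
(1200 genes total) with the δ = 0.5 effect, and the null calibration
re-draws expression noise 200 times over a fixed gene population — sizes
chosen so the group tests are decisively powered while the whole suite runs
in seconds. The chloroplast-style census in the acceptance script runs on a
synthetic population constructed with 14 tandem genes (runs 3–4) among 80,
mirroring the structure of an organellar census; analysing a real organelle
requires supplying its CDS FASTA (`read_cds_fasta` + `census_tandem_genes`).

## Known limitations

* The chloroplast codon set is rule-dependent and intentionally not pinned.
* The DE p-value test on two replicates per condition has little power; the
  three-way conjunction is deliberately conservative, and the package makes
  no claim about which engine produced any published adjusted p-values.
* TE is undefined for genes with any zero input/footprint replicate; no
  shrinkage or imputation is attempted.
* Malc quantification assumes complete digestion outside the probe-protected
  span and ignores capture-efficiency differences between fragments.
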