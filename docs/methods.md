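# Methods

## The cross and its simulation

The simulated design is a two-parent yeast cross: a high-fermentation-
capacity founder (parent A) and a low-capacity founder (parent B), both
haploid. F1 haploids are meiotic products of the A×B hybrid; each F2
diploid is formed by mating two independently drawn F1 haploids, and one
haploid spore per F2 diploid enters the segregant population (tetrad
structure is not retained — nothing downstream uses it). The default
population size is 133 segregants, with two phenotype-extreme pools of 15.

Meiosis uses the Haldane model: crossovers form a Poisson process along the
genetic map, so the recombination fraction between adjacent markers at map
distance d Morgans is r = (1 − e^(−2d))/2, and each chromosome starts from
either parental strand with probability ½. The genetic map is a uniform
0.35 cM/kb — a standard yeast-scale figure — over the real S288C chromosome
lengths; marker positions are evenly spaced within chromosomes, 6,318
biallelic probe-pair loci in total. Uniform rate and spacing are
assumptions: the real array's marker density varies, and yeast
recombination is hotspot-structured. Neither matters for the statistics
tested here, which depend on map length, not its local texture.

## Phenotype model

Phenotype (g/L CO₂ at the 89-h checkpoint) is additive: baseline plus an
effect per QTL carried, plus Gaussian environmental noise. The default
architecture plants four loci — chrVII:683 kb (effect 1.2, beneficial
origin B), chrVII:748 kb (4.0, A), chrXIII:450 kb (1.0, B), chrXIV:400 kb
(0.8, B) — so three of four beneficial alleles come from the *weaker*
parent, and the two chrVII loci have opposite directions. Under additivity
the single A-beneficial effect must exceed the summed B effects for parent
A to actually be the higher parent; hence the 4.0 vs 1.2+1.0+0.8 split.
Baseline 25 g/L puts values in a realistic nitrogen-limited range.

Environmental noise is calibrated, not fixed: given the realized genetic
variance Vg of the population, the noise sd is σ = √(Vg(1−H²)/H²) so the
expected broad-sense heritability equals the target (default 0.98).
Parental replicate measurements (default 3 per parent) share this σ unless
`env_sd_parent` overrides it; when Vg = 0 the override is also the
segregants' noise sd, since the calibration is then vacuous.

One consequence the simulator does **not** hide: with beneficial alleles
split 3/1 between parents, both parents sit well inside the segregant
range, so transgression on synthetic data is massive (~50% per side at
H² = 0.98) rather than the few-percent level seen in real crosses of this
kind, where dominance, epistasis and shared haplotype blocks compress the
segregant distribution. Transgression arithmetic is therefore tested on
constructed inputs, not on generator output.

## Fermentation curves and rate estimation

Simulated cumulative CO₂ is a growth-phase ramp (Gaussian saturation,
~18 h scale) times a slowly rising stationary term, scaled so the noiseless
curve passes exactly through the planted phenotype at the checkpoint;
sampling every 20 min (268 points over 89 h). Measurement noise is additive
on the sampled values.

`co2_from_mass` converts mass loss to CO₂ and clamps transient mass *gains*
up to the weighing precision (default 0.1 g, the conservative end of the
0.1–0.01 g instrument range) to the running maximum; larger gains raise an
error rather than being silently flattened. `co2_rate` fits a second-order
polynomial to the trailing window of 10 points and evaluates its analytic
derivative at the window's last time — trailing, not centred, matching
"the last n measurements" online-monitoring practice; the first 9 positions
are NaN by design. The time variable is centred on the evaluation point
before fitting, so the estimate is shift-invariant and numerically stable.
A degree-2 fit is exact for quadratic cumulatives (tested to 1e-9 relative).

## Population statistics

Var_env is the df-weighted pooled variance ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2);
H² is reported unclipped with a flag when Var_env > Var_seg, rather than
truncated to 0 — a negative estimate is information. Transgression bounds
are inclusive (≥ 2σ beyond the nearer parental mean). Bulk selection breaks
phenotype ties by strain id (ascending for the low bulk, descending for the
high bulk) so repeated runs select identical pools even on degenerate data.

## Signal model and the scan

Pool signals are linear in pool allele frequency: a pool with A-allele
frequency f at a probe has expected normalized allelic difference
d = 3f − 1.5, so pure parental pools sit at ±1.5 and a balanced pool at 0.
Each probe emits one value per replicate block (default 8) with Gaussian
noise sd 0.1. This is the simplest model consistent with reading extreme
hybridization intensities as near-fixation of one parental allele; it
ignores dye effects, probe-specific affinity and spatial artifacts, which
the per-block centring and parental-anchor normalization are designed to
remove in real data anyway.

The normalization solves one gain and one offset from the two parental
grand means and applies them to every sample, making the parent means
exactly ±1.5 (to numerical tolerance ~1e-9, checked as an invariant). The
probe filter is a one-tailed Welch t-test (A > B) over replicate blocks,
BH-adjusted across probes. The window test is paired across the window's
probes: one bulk_high − bulk_low mean difference per probe, a one-sample t
against zero per 20-probe window (step 1, maximally overlapping; a
chromosome with fewer informative probes than the window yields a single
flagged truncated window), BH-adjusted genome-wide. Region calling retains
probes covered by a significant window whose absolute bulk difference also
exceeds `parental_fraction` (default ⅓, with ½ as the stricter preset)
times the local parental difference, then merges runs bridging up to 2
non-retained probes. Direction of effect per bulk is the sign of its mean
d over the region: positive = parent-A alleles enriched.

## What the scan can and cannot do at this bulk size

With 15-member bulks the allele-frequency difference between pools at a
*neutral* locus has sd ≈ √(2·0.25/15 · (133−15)/(133−1)) ≈ 0.17, and the
frequency process decorrelates along a chromosome only over ~25 cM
(~70 kb here). About 6% of the genome therefore exceeds the ⅓-of-parental-
difference gate by drift alone, in dozens of quasi-independent segments —
and because probe noise (0.1 over 8 blocks) is small compared with such
persistent offsets, the window t-test flags essentially every drift
excursion as significant. Planted QTL are reliably the strongest signals
(largest |bulk difference|, smallest p), but they are accompanied by tens
of drift regions per genome; ranking or raising `parental_fraction` is
required to shortlist, exactly as manual inspection is required on real
data of this design. A further structural effect: a small-effect locus
closely linked to a large opposite-direction locus (the two chrVII defaults
are 22 cM apart) has its enrichment partially cancelled by linkage drag and
is the locus most often missed. Both behaviours are properties of the
design (bulk size, threshold), not of the implementation.

## Numerical and interface choices

* Coordinates are 1-based inclusive in all TSV interfaces; BED output is
  0-based half-open (span [s, e] → (s−1, e]).
* Missing values are written as "NA"; floats with 12 significant digits, so
  read→write→read round-trips are byte-stable.
* Zero-variance windows (possible only with noiseless synthetic input) get
  p = 0 when the mean difference is nonzero, p = 1 otherwise.
* Degenerate inputs raise typed errors: equal parental means
  (normalization), zero segregant variance (H²), single replicate blocks
  (probe test), checkpoint outside the measured range.
* The pipeline fans one global seed into named per-stage substreams
  (`SeedSequence(seed, spawn_key=(stage,))`), so stages are independently
  reproducible and a rerun with the same config is byte-identical,
  including the manifest (no timestamps).

## Problem sizes used by the test suite

Unit tests run on a 320-marker map (structure-preserving, 16 chromosomes);
calibration and end-to-end properties run at full scale — 6,318 markers,
133 segregants, 20 seeds — which completes in well under a minute for the
heritability recovery and tens of seconds for the full scan property.
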