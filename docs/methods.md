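# Methods

## Model and assumptions

The package treats a pooled CRISPRi selection as exponential lineage
competition in a turbidostat. Each (guide, barcode) lineage has a raw
relative growth rate ρ (doublings per generation; the non-targeting
reference defines ρ = 0) and abundance A(τ) = A(0)·2^{ρτ}, with
τ = hours × mixed-population doublings·h⁻¹. Sequencing at each scheduled
timepoint is a single multinomial draw of fixed depth over all lineages.
Escape events — loss of CRISPRi activity through sgRNA or dCas9
mutation — switch a lineage to ρ = 0 from a uniformly drawn time onward;
one switch per lineage, full reversion.

Knockdown strength enters through a gene- and environment-specific
four-parameter Hill curve in the number of compounding spacer mismatches,

    g(m) = min + (max − min) · m^Hill / (IG50^Hill + m^Hill),

on the normalized growth scale (0 = complete kill, 1 = wild-type). The
fitter uses the same functional form, which makes parameter recovery
well-posed; the flat-curve rule and all bounds follow the analysis
defaults below. Single and double mismatches act through per-position
knockdown-retention factors: the retained knockdown of a variant is the
product of its positions' factors, so growth is
min + (max − min)·(1 − Π retention). Raw and normalized scales are linked
by ρ = g·|floor| − |floor| with the lethal floor at −1.23 doublings per
generation.

## Defaults that matter

| parameter | default | notes |
|---|---|---|
| schedules | glucose 0–14 h at {0,2,4,6,10,12,14}; glycerol {0,2,6,10,14} | hours; the glycerol run sequences fewer points |
| doublings·h⁻¹ | 0.94 glucose, 0.53 glycerol | rescales hours to generations so environments are comparable |
| sequencing depth | 10⁶ reads/timepoint in benchmarks | multinomial, no overdispersion by default |
| escape probability | 0.01 per lineage | a free simulator knob; escaper rates are not quantified per lineage in published data |
| replicate jitter | 0.01 (SD on ρ) | biological variation between barcoded replicates, truncated so normalized growth stays in [0, 1.15] |
| depth floor | 10 counts | fits include the first sub-floor point, none after |
| R² filter | 0.70, exempting slopes in [−0.05, 0.05] | R² is uninformative near zero slope |
| Dixon Q | two-tailed 95%, n = 3–10 (Rorabacher 1991 r10 table) | single pass, at most one removal per guide |
| min replicates | 3 of 6 | guides below this are rejected, not errored |
| SGoF | exact binomial, one-tailed, γ = α = 0.05, fixed n | pool sizes here are modest, so the exact tail is used rather than a large-n approximation |
| logistic fit | starts (meanL, meanH, 1, 6); min/max ∈ [0, 1.15], IG-50 ∈ [0, 14], Hill unbounded; ≥8 points | flat when \|meanH − meanL\| < 0.05 (strictly) |
| sequence filters | 0.45 < GC < 0.80 (strict), max T-run 4 | applied to the 20-nt spacer, including non-targeting controls |
| truth curves | min ~ U[0, 0.55], max ~ U[0.9, 1.1], Hill ~ U[1.5, 4], IG-50 ~ U[4, 10] | one realistic draw per gene/environment; seed region retention 0.85–1.0, distal 0.05–0.6 |

## Design conventions

PAMs are scanned as CCN on the sense strand; the protospacer is the 20 nt
immediately 3′ of the motif and the spacer its reverse complement, so
spacer position −1 is the PAM-proximal base. Offsets are 1-based at the
first C; "within the first 150 bp" means pam_offset ≤ 150 and "at least
200 bp downstream" means pam_offset ≥ 200. SG2 is the next-closest
candidate whose protospacer window does not overlap SG1's. Off-target
screening compares 20-nt windows on both strands of user-supplied
background sequences; "adjacent to a PAM" allows the motif within 3 nt of
the window's PAM-proximal end in the matching orientation. The three
redesign rules are applied exactly as stated (a lone perfect site is the
intended target); a site at exactly 90% homology falls between rule ii
(> 90%) and rule iii (< 90%) and, deliberately, fires neither.
Non-targeting controls pass the same GC/poly-T filters as targeting
guides, for manufacturability parity.

## Numerical choices

**Zero counts.** A zero count at an interior timepoint makes f undefined;
the fit truncates before such a point (the sub-10 rule extended to its
limit). Lineages with a zero count at t = 0 are dropped with a warning.

**Reference selection.** The reference control is the non-targeting guide
with the median provisional slope (log2 share of total reads against
hours, barcodes pooled), restricted to controls with a nonzero count in
every barcode at every timepoint; lower median on even counts, smallest
id on ties.

**The normalization floor.** The floor anchors the entire normalized
scale, so it gets a likelihood-based estimator: among parent guides that
kept all internal replicates, the barcode-pooled count trajectories are
refit by Poisson maximum likelihood (expected counts A·2^{ρτ} times the
reference trajectory as offset), and the floor is the median of the five
most negative slopes. Log-ratio OLS on lethal lineages is biased by the
logarithm of single-digit counts, and taking the single most negative of
~160 noisy parent means anchors the scale on an extreme order statistic;
both effects were large enough to shift every normalized value by up to
0.1. Per-guide statistics keep the published OLS + truncation rule.
When two environments are analysed together, the first environment's
floor is reused for the second — one anchor, directly comparable scales;
independent floors were observed to inject spurious min-parameter
differences between environments.

**Clique search.** "Mutually distinguishable" is formalized as a clique
(every pair significant). The solver is an exact branch and bound over
bitsets with a greedy-coloring bound; the maximum size is always exact,
and maximum cliques are enumerated (capped at 20 000) for the tie-break
by dynamic range, then variance of means, then guide ids.

**Logistic evaluation.** The Hill curve is evaluated as
1/(1 + (IG50/m)^Hill) with explicit limits at m = 0 and IG-50 = 0, which
stays finite for any sign of Hill (Hill is unconstrained in the fit).

**Flat-versus-sigmoidal genes.** In interaction calling, an environment
"titrates" when at least two of its replicate fits are sigmoidal. A gene
sigmoidal in exactly one environment gets p = 0 for IG-50 and Hill — a
present-versus-absent titration is an unambiguous difference — and p = 0
entries are always included in the SGoF rejection set.

**Read counting.** The strict Q > 30 filter applies to the spacer and
barcode bases by default (switchable to the whole read); spacer and
barcode matching is exact, with no 1-mismatch rescue.

## What the synthetic benchmarks show — and what they do not

The generator reproduces the quantities the analysis consumes: graded
growth effects, barcoded replicates, escaper dynamics, multinomial
sampling noise, and the two environment schedules. Passing benchmarks
therefore demonstrate that the estimation pipeline inverts the generative
model it states — escaper-corrected slopes recover planted growth rates
(96.9% of compact-library guides within ±0.05 at depth 10⁶, seed 1), the
replicate filters catch planted escapers (86% of scorable events), and
planted IG-50 shifts surface as titration-only interactions with few
false calls.

They do not demonstrate robustness to what the generator omits: PCR and
sequencing count overdispersion (a Dirichlet-multinomial knob exists but
is off by default), sequence-context dependence of mismatch effects
(retention factors are position-only), lag phases or induction kinetics,
partial escape, and barcode cross-talk. Real-data behaviour on those axes
is untested here.

Two identifiability limits are worth knowing. First, the compact
16-guide library measures mismatch counts {0, 4–10}, so IG-50 values
near or above the top of that grid are weakly identified: the median
absolute IG-50 error is ~0.3 mutations, but individual high-IG-50 genes
can miss by more. Second, SGoF rejects only the *excess* of sub-γ
p-values over the binomial null — with n pooled tests it rejects
F − (k*(n) − 1) of the F sub-γ values — so in small pools a handful of
genuine effects always remain uncalled regardless of effect size. Both
are properties of the measurement design and the published correction,
not of the implementation.

## Problem sizes

The recovery benchmark runs 88 genes × 16 compact guides × 6 barcodes ×
7 timepoints at depth 10⁶ (jitter 0.01, escape 0.01); the escaper
benchmark 12 genes with escape probability 0.08; the interaction
benchmark 20 genes × the 15-guide SG1 series × 6 barcodes in both
environments at jitter 0.02. All three, plus the oracle-equivalence and
solver-exactness suites, complete in well under a minute on one CPU.
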