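# Methods

## The scientific question

Flavoprotein amine oxidoreductases (FAOs) oxidize C–N bonds of amine
substrates via their FAD cofactor and then must reoxidize the reduced
flavin (FADH₂). The textbook assumption is that O₂ is the electron
acceptor (oxidase activity, producing H₂O₂), but several bacterial FAOs
instead pass the two electrons, one at a time, to a cytochrome *c* (CytC)
encoded next to them in the genome (dehydrogenase activity). This package
implements the complete desk-side analysis that distinguishes the two
behaviors: a mechanistic simulator and fitter for stopped-flow
reoxidation kinetics, a rule-based oxidant-preference classifier, a
genomic screen for the two "signposts" of dehydrogenase function (a
twin-arginine export signal on the FAO, an adjacent CytC gene), and
maximum-likelihood ancestral reconstruction of those operon
configurations on a phylogeny.

## Kinetic model (`kinetic_core`)

The oxidative half-reaction is modelled with mass-action kinetics over
seven species (three enzyme flavin states, oxidized/reduced CytC, O₂,
H₂O₂):

* O₂ branch (irreversible): `E·FlH₂ + O₂ → E·Fl_ox + H₂O₂`, rate
  constant `k_o2` (M⁻¹s⁻¹). H₂O₂ is tracked as an inert product.
* CytC branch (two reversible one-electron transfers through the flavin
  semiquinone): `E·FlH₂ + C_ox ⇌ E·FlSQ + C_red` (forward `k1f`) and
  `E·FlSQ + C_ox ⇌ E·Fl_ox + C_red` (forward `k2f`).

Only the forward constants are measurable from the k_obs slopes; the
experiments establish reversibility (trace amplitudes titrate with CytC
and an equilibrium is reached at sub-stoichiometric CytC) but not its
magnitude. Reverse constants are therefore parameterized as
`kif / Ki` via per-step equilibrium constants `K1`, `K2` (default 10,
configuration not data; `inf` = irreversible). The scheme assumes
sequential CytC binding at a single site (no ternary complexes).

All concentrations are post-mix values: the stopped-flow mixer dilutes
1:1, so 36 µM tonometer enzyme is 18 µM observed and 80–160 µM syringe
CytC is 40–80 µM observed.

Integration uses the stiff BDF solver with an analytic Jacobian,
rtol 1e-8 and atol 1e-12 M. Concentrations in (−1e-12, 0) M — within the
solver's absolute tolerance — are clipped to zero; anything more negative
is treated as solver failure. Equilibrium endpoints are computed by
integrating over successively longer horizons and polishing with a
Newton solve of the two equilibrium conditions under the three
conservation laws (enzyme, cytochrome, electron count).

Observables are Beer–Lambert sums. Measured coefficients: ε₄₅₀ = 11300
M⁻¹cm⁻¹ for oxidized FAD (used for enzyme quantitation) and ε₄₁₀ =
106000 M⁻¹cm⁻¹ for CytC. The remaining coefficients are documented,
overridable assumptions: ε₄₅₀(FlH₂) = 900, ε₄₅₀(FlSQ) = 4000, and at
550 nm a single reduced-minus-oxidized heme difference coefficient of
21000 M⁻¹cm⁻¹ with ε₅₅₀(C_ox) folded to 0. ε₅₅₀(FlSQ) defaults to 0;
setting it positive (e.g. 4000) reproduces the observed ~60/40 amplitude
split between the two CytC phases, because semiquinone forms in the
first electron transfer and decays in the second — with it at 0 the
split is 50/50 at saturating CytC (each phase moves one electron).

## Trace fitting (`trace_fit`)

Traces are fit to `Y = ΔA·exp(−k_obs·t) + A_∞` or the two-phase sum, by
nonlinear least squares with rates optimized on a log scale (positivity
by construction). Initialization was genuinely open; the package uses a
single-exponential fit of the whole trace as an anchor, a log-spaced
grid of fast/slow rate splits around it, plus a classical tail-peeling
start, and keeps the best of ~8 starts. The boundary of the log-rate
parameterization is treated as degenerate and such starts are discarded.
On noiseless synthetic data recovery is exact to ≤1e-6 relative.
Reported phases are ordered fastest first (`k_obs1 > k_obs2`), matching
the convention that the first electron transfer is the faster one.

Phase-count selection returns two phases only when the small-sample
corrected information criterion improves by more than 10 AND both
amplitudes exceed 3× the residual noise of the two-phase fit; a
single-phase fit that already explains the trace to numerical precision
short-circuits to 1. The margin and floor are configuration.

`k_obs` values are regressed against oxidant concentration by ordinary
least squares; the slope is the bimolecular constant `k_ox` and the
intercept is retained (not forced through zero). The full time range of
each trace is fitted; baseline alignment of overlaid CytC traces is a
plotting aid only and is never applied before fitting.

`pseudo_first_order_bias` quantifies what limited oxidant excess does to
this pipeline: it simulates exact second-order traces at given
concentrations, fits the biexponential, regresses, and reports
`(slope − k1f)/k1f`. At the experimental regime (18 µM enzyme, 40–80 µM
CytC, only 2–4× excess) the slope underestimates the generating constant
by ~1–2%, i.e. reported dehydrogenase constants are conservative. The
decay of the bias with excess is not monotone in sign: simulations show
a small positive overshoot (≲1%) at intermediate excess, an artifact of
approximating a second-order trace with a biexponential, before the bias
vanishes (|bias| < 1e-4 at ≥40× excess). The tests therefore assert the
sign in the limited-excess regime and the monotone decay of |bias|.

## Preference classification (`oxidant_classify`)

The published verdicts are verbal; the classifier makes the reasoning
explicit with auditable thresholds (all configurable, each call carries
the rule that fired):

* dehydrogenase: `k_ox1^CytC / k_ox^O2 ≥ 100` (observed dehydrogenases
  span ~290 to >10⁴);
* dual: O₂ rate ≥ 10³·⁵ M⁻¹s⁻¹ (oxidase-like) with CytC ratio in
  [1, 100);
* oxidase: no CytC constants and O₂ rate ≥ 10⁴ M⁻¹s⁻¹ (the bona fide
  oxidase range is ~10⁴–10⁶; free FAD reacts at ~250);
* indeterminate: everything else — notably slow-O₂ enzymes paired with
  membrane-bound c4-type cytochromes, whose solution kinetics
  understate the in-vivo reaction, and TAT-exported enzymes with no
  adjacent CytC and slow O₂ rates, which may use an unknown periplasmic
  oxidant.

Applied to the 27 published rate-constant rows bundled in
`reference_data`, the rules reproduce every verbal assignment.
Classification is monotone in the intended directions (raising the CytC
constant never demotes a call; the ratio rule is scale-free).

## Genomic screen (`signpost_scan`)

Signal peptides use motif heuristics rather than a trained predictor:
transparent, testable, and sufficient for synthetic fixtures (real-data
users can substitute an external predictor through the `SignalCall`
interface). TAT: the consensus `[S/T]-R-R-x-Φ` (Φ hydrophobic) within
the first 35 residues followed within 25 by ≥6 consecutive hydrophobics.
Sec: no TAT call, a K/R in positions 1–7, ≥7 consecutive hydrophobics in
positions 5–25, and an A-x-A cleavage motif in positions 15–35 (the PelB
peptide cleaves at 22 under these rules). The two calls are mutually
exclusive by construction.

C-type cytochromes are recognized by non-overlapping CXXCH
heme-attachment motifs: one motif with mature length ≤130 aa is a class
I monoheme (~11 kDa); two motifs at 150–250 aa a c4-type diheme
(~20 kDa); other combinations are not called, trading recall for the
precision the category assignment needs.

Operon categories: green if the FAO itself is a fusion (TAT, length
≥450 aa, CXXCH in the C-terminal 150 residues); else blue if TAT plus a
CytC gene within the adjacency window; else red if TAT only; else black.
"Immediately upstream/downstream" is quantified as ≤3000 bp between gene
boundaries with ≤2 intervening genes, strand-agnostic — both choices are
configuration. Coordinates are 1-based inclusive (GenBank dialect).

Pairwise identity is global alignment (match +1, mismatch −1, gap open
−2, extend −0.5) with matches divided by aligned columns, counting
internal gap columns and excluding terminal overhangs; the deduplication
is greedy single-linkage in input order at the >98% cutoff,
deterministic and idempotent.

## Ancestral reconstruction (`ancestral_mk`)

The four categories evolve under the equal-rates Mk model (k = 4,
configurable) with the closed-form transition probability
`P_ii(t) = 1/k + (k−1)/k·exp(−αkt/(k−1))` and a uniform root prior —
the simplest model consistent with a four-state encoding; nothing in the
data motivates unequal rates. The rate α (per unit branch length; the
branch-length unit is whatever the input tree uses) is estimated by
bounded 1-D maximization of the pruning likelihood on a log₁₀ scale over
[1e-6, 1e3]; monomorphic tip data return the lower bound with a flag.
Marginal node probabilities use the standard two-pass inside/outside
algorithm with per-node rescaling. Plotting states are the marginal
argmax with ties broken toward the parent's state then lexicographically
(deterministic output), and transition counts — the proxy for
independent origins of each configuration — count edges whose argmax
states differ. This undercounts multiple hits on one edge and is
documented as an approximation; on simulated histories the count never
exceeds the true number of change events. Structurally impossible data
(conflicting tips across zero-length branches) report −inf rather than
an exception from the likelihood.

Correctness is anchored to a brute-force enumeration oracle (sum over
all internal-state assignments) on trees of ≤6 tips, agreeing to 1e-10.

## Synthetic data (`synth_data`)

The generators define the study conditions:

* Traces: the mechanism simulator plus i.i.d. Gaussian absorbance noise,
  σ = 0.002 AU by default — a plausible photometric noise floor; no
  dead-time, photobleaching or baseline drift. O₂ ladders use the
  measured dissolved-O₂ range (130–605 µM post-mix); CytC recovery runs
  use 200–800 µM at 1 µM enzyme so the pseudo-first-order assumption
  holds, while bias studies deliberately use the experimental 40–80 µM
  at 18 µM enzyme. Grids are 400 points, linear for single-phase O₂
  traces and log-spaced for biphasic CytC traces.
* Genomes: random 20-letter proteins with the diagnostic motifs planted,
  and accidental RR pairs near the N-terminus or stray CXXCH motifs
  scrubbed, so the planted truth is the only signal; the blue
  configuration reproduces the exemplar FAO–CytC–FAO operon. Written as
  GenBank flat files with random-nucleotide filler of consistent length.
* Trees: Yule trees (dendropy) with tip edges extended by the waiting
  time to the next unrealized speciation (keeps the tree ultrametric
  and terminal branches strictly positive), and the character evolved
  with exponential waiting times at total rate α, full history recorded.

Because the sequences are random with planted motifs, a perfect screen
score shows the rules fire exactly as specified — not that the
heuristics match a trained predictor on real proteomes. Likewise the
kinetic recoveries show the fitter inverts the generating mechanism, not
that real instruments are noise-free.

## Problem sizes and tolerances

Recovery runs use 4-concentration ladders of 400-point traces (seconds
each); enumeration oracles cap at 6 tips (4⁵ assignments); rate-recovery
simulations use 64-tip trees; the stationarity check uses 200 tips. The
acceptance script reruns the four rate-constant recoveries from scratch
in a few seconds. Noiseless round-trips are asserted at 1e-6 relative,
enumeration agreement at 1e-10, recovered slopes at 2%, and the noisy
regression fixture at 5% with a fixed seed.

## Known limitations

* Reverse-rate magnitudes and semiquinone extinctions are assumptions;
  conclusions that depend on them (equilibrium endpoints, the 60/40
  explanation) are qualitative.
* The signal-peptide heuristics are motif rules, not SignalP; on real
  proteomes expect both false positives and negatives.
* The Mk reconstruction assumes equal rates and a given rooted tree;
  tree inference, bootstrap support and topology tests are out of scope.
* Product-bound rate enhancement (e.g. the ~27-fold effect seen in one
  oxidase) is representable only as two separate schemes.
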