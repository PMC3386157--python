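# Methods

## The nucleotide-cycle model

A Gα subunit is treated as a two-state enzyme: GDP-bound (inactive) and
GTP-bound (active). Two pseudo-first-order rate constants govern the cycle:

- `k_exchange` (min⁻¹): the apparent rate of GDP release/GTP(γS) binding
  measured in a [³⁵S]GTPγS filter-binding assay or by the rise of intrinsic
  Trp fluorescence. GDP release is assumed rate limiting within this step,
  with subsequent GTP binding fast, so one constant suffices.
- `k_cat` (min⁻¹): the intrinsic single-turnover hydrolysis rate, measured
  by Pi release from preloaded [γ-³²P]GTP.

From these two constants the model derives the quantities used to classify
regulation. The steady-state active fraction,
`f = k_exchange/(k_exchange + k_cat)`, follows from the two-state master
equation at excess GTP. The multi-turnover rate per Gα treats the steps as
first-order processes in series, `v = (1/k_exchange + 1/k_cat)⁻¹`; the same
value emerges as the asymptotic Pi slope of the turnover ODE at saturating
GTP, which is checked as an internal consistency property. The rate-limiting
step is simply the slower rate, with rates within 5% of each other reported
as "balanced" — no measured protein falls in that band (the closest case is
a ratio of ~2), so any band below 2× yields the same classifications.

Assumptions worth stating: exchange is irreversible on the assay timescale
(quenched filter binding); hydrolysis is irreversible; Trp fluorescence is
taken as proportional to the GTP-occupied fraction (a convention adopted for
simulation, not independently tested); temperature effects are absorbed into
the constants (all reference values are 20°C measurements).

## Finite-GTP turnover ODE

The fluorescence experiment adds a finite GTP pool (e.g. 800 nM GTP on
400 nM protein), so product GDP accumulates and competes for rebinding.
The model is

```
d(gGTP)/dt = k_exchange · (g_total − gGTP) · φ − k_cat · gGTP,
φ = GTP_free / (GTP_free + GDP_free)
```

with each productive exchange event consuming one free GTP and releasing one
free GDP, and hydrolysis converting bound GTP to bound GDP in place while
cumulative Pi is tracked. The competition factor φ is the simplest
mass-action account of GTP/GDP rebinding competition; it is a model choice
validated only by qualitative shape properties (a single interior maximum of
the active fraction followed by decay under hydrolysable GTP; a monotone
rise to full occupancy under a non-hydrolysable analog). Free nucleotide
total is conserved exactly by construction and verified to relative 1e-6 in
every trajectory. Effective reactive protein is nominal concentration times
the preparation's specific activity (0.46–0.69 mol/mol for the reference
preparations); initial free GDP is zero (the assay buffer contains none —
the GDP carried on loaded protein enters the pool on first exchange).

Integration uses LSODA (stiff-capable, adaptive) with rtol 1e-8 and atol
1e-10 nM; the rates span ~0.02–7 min⁻¹, so stiffness is mild but the tight
tolerances make the mass-conservation and occupancy-equivalence checks
meaningful. With φ pinned at 1 (unlimited GTP) the long-time active
fraction equals the closed-form `f` to 1e-4 absolute, an equivalence tested
across all reference parameter sets.

## GAP (RGS) action

RGS acceleration of hydrolysis is modelled as a hyperbola,
`k_obs([RGS]) = k_cat + k_gap_max·[RGS]/(k_half_gap + [RGS])`, fitted from
dose–response points that must include a zero dose (otherwise `k_cat` is
unidentifiable). No published half-maximal concentration anchors
`k_half_gap`, so it has no default and must be supplied or fitted. A fitted
`k_gap_max` below 10% of `k_cat` flags the protein RGS-insensitive — the
behaviour of a Gα whose intrinsic hydrolysis is already fast. At the
steady-state level, fold-acceleration `v_plus/v_minus ≥ 1.5` counts as GAP
stimulation; the threshold separates the non-stimulated liverwort case
(≈1.07) from the weakest stimulated case (≈5) by a wide margin and is a
reporting heuristic, not a mechanistic claim. Likewise the
"self-inactivating" flag (`k_cat ≥ 0.5 min⁻¹`) separates the fast-hydrolysis
liverwort protein (0.87) from the slow eudicot/grass proteins (~0.05).

## Fitting

All nonlinear fits are damped least squares (lmfit/MINPACK) on analytic
model functions. Exponential fits start from `k₀ = ln2 / t_half-max` and try
three log-spaced initial rates (k₀/5, k₀, 5k₀), keeping the best
sum-of-squares, which removes the local-minimum risk at the parameter ranges
involved. Replicates are pooled into one residual vector rather than
averaged first, preserving the error structure. Reported standard errors
are the covariance-based fit SEs; simulation tests additionally check that
the seed-to-seed spread of estimates is of the same order.

The steady-state rate is the slope of an ordinary linear regression (with
intercept, which absorbs the brief pre-steady-state lag of duration
`~1/(k_exchange + k_cat)`) over the initial window, defined as points with
cumulative Pi at most 20% of the initial GTP pool; the slope divided by the
Gα concentration gives the per-protein turnover.

SPR sensorgrams follow the 1:1 Langmuir model: association
`R(t) = R_eq(1 − e^{−(k_a C + k_d)t})` with `R_eq = k_a C R_max/(k_a C + k_d)`,
dissociation exponential at `k_d`. The global fit shares `k_a`, `k_d` and
(by default) `R_max` across the dilution series — one immobilized surface —
with per-curve `R_max` available for drifting surfaces; because dissociation
is concentration-independent, `k_d` survives per-curve capacity drift, a
property covered by test. Rates are fitted in log10 space within generous
bounds, with the dissociation-tail decay seeding `k_d` and a three-point
grid seeding `k_a`. A series whose maximal response stays below 3× the
noise SD (estimated from median absolute successive differences) is reported
as a non-binder instead of being fitted. `R_max` is instrument-specific and
not part of the published constants; simulations use a nominal 100 RU.

Time units are minutes for enzymology and seconds for SPR, converted
explicitly at call sites; concentrations are nM for enzymology, M for SPR.

## Sequence determinant and dN/dS

The switch-I determinant is mapped by Needleman–Wunsch global alignment
(BLOSUM62, gap open 10, extend 0.5, end gaps penalized; Biopython's
deterministic first-optimal traceback) from reference position 194 onto the
query, then classified by residue identity alone: Thr or Ser →
RGS-couplable (Ser is accepted as a conservative substitution at the
hydrogen-bonding site, an extension beyond the strict Thr/Asn/Lys
discussion), Asn → grass-type uncoupled, Lys → Gα12/13-like, gap →
unaligned, anything else → other. Alignment optimality is tested against
exhaustive enumeration of all alignments for short sequences, and position
mapping is tested to round-trip.

dN/dS is the Nei–Gojobori (1986) pathway-counting estimator: per-codon
synonymous site counts are the fraction of one-step changes preserving the
amino acid (changes creating stop codons count as nonsynonymous, so S+N=3
per codon exactly); differences average over all minimal substitution
pathways with equal weight, excluding pathways through stop codons (falling
back to inclusion if all are blocked); proportions are Jukes–Cantor
corrected, `d = −¾ ln(1 − 4p/3)`, flagged undefined at p ≥ ¾; `dS = 0` with
`dN > 0` reports an infinite ratio with a flag. Codon columns with gaps,
stops or ambiguous bases are skipped and counted. Regions are named 1-based
inclusive codon intervals. Published domain-wise dn/ds values for the
foxtail-millet RGS locus are not reproducible here because the underlying
sequences and alignment choices are unavailable; the estimator is validated
by hand-enumeration oracles on single-codon pairs and by
pure-synonymous/pure-nonsynonymous construction properties instead.

## Synthetic data

Generators exist for every assay and are the package's test bed: exponential
GTPγS association with plateau = concentration × specific activity;
single-turnover Pi release; ODE-based multi-turnover Pi accumulation;
seven-concentration Langmuir sensorgram series (6.25–400 nM, 3 min
association, 5 min dissociation, 1 s sampling). Default noise is 3%
multiplicative Gaussian for scintillation-counted traces (5% used in the
hydrolysis-recovery studies) and 0.5 RU additive for SPR — magnitudes chosen
as realistic for the instruments, since none are published — and every
generator is bit-reproducible under a fixed seed. Default sampling covers
five half-lives of the process (capped at 60 min): 10 log-spaced points for
fast rates (≥1 min⁻¹), 12 linear points otherwise.

The synthetic Gα family generator produces variants of a bundled reference
with an exact count of grass-type members (Asn at the determinant site),
uniform random substitutions elsewhere (rate capped at 0.2/site to keep
alignments reliable), and seeded uniform-synonymous back-translated coding
sequences. The bundled reference sequences are deterministic synthetic
stand-ins, not database records: they reproduce the positional geometry of
the eudicot/grass pair (determinant at 194 mapping to 195 across a
one-residue insertion) but not real Gα sequence content, so sequence-level
results on them demonstrate the machinery, not biology of any particular
gene.

What passing tests show — and do not. Noise here is independent Gaussian;
real assays have correlated drift, baseline artifacts and pipetting error,
and real SPR has bulk refractive-index jumps (available only as an optional
additive constant) and mass-transport limitation (not modelled). Parameter
recovery within 5% under these conditions therefore demonstrates estimator
correctness, not expected accuracy on bench data. The in-vitro steady-state
statistics also do not extrapolate to cells, where GTP/GDP ratios and
interacting proteins shift the balance.

## Problem sizes

Simulation-based checks use 20 seeded replicates per condition with 10–14
time points per trace, and the acceptance recomputation uses 20 replicate
progress curves (500 nM Gα, 20 µM GTP, 14 points over 8 min, 5% noise) —
sizes at which estimator bias and seed noise are both comfortably below the
5% acceptance band while each study runs in seconds.

## Known limitations

- One published steady-state minus-RGS rate set sits ~2× below the
  series-model prediction from the corresponding exchange/hydrolysis rates;
  the two-step series model is an idealization and the package does not
  attempt to reconcile the discrepancy.
- `k_exchange` conflates GDP release and GTP binding; no GDP-affinity or
  GEF/GDI kinetics are modelled, and heterotrimer (Gβγ) effects are out of
  scope.
- The balanced/self-inactivating/stimulation thresholds are reporting
  heuristics chosen to separate the observed cases, documented above.
- dN/dS assumes equal mutation rates among nucleotides (Jukes–Cantor) and
  unweighted pathways; no transition/transversion correction is applied.
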