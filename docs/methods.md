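# Methods

`torsioncouple` models how transcription of one gene changes the expression
of its neighbors through DNA torsional stress, and provides a genomics
pipeline for testing the signatures of that coupling in annotation +
expression data. This note records the model, its assumptions, the
numerical choices, and what the synthetic data do and do not emulate.

## 1. Transcription-generated torsion field

An elongating polymerase over-winds the DNA ahead of it and under-winds it
behind (the twin-supercoiled-domain picture). Averaging over time and
assuming topoisomerases relax excess torsion outside the gene with uniform
per-base efficiency `1/b`, the stationary perturbation of superhelical
density at distance `d` from the nearer edge of a transcription unit is

    dsigma(d) = ± sigma_a · exp(−d/b),        sigma_a = alpha · k · l,

positive downstream of the 3′ end, negative upstream of the TSS. Fields of
several genes superpose additively on the basal level `sigma0`.

Parameters (units, default, why):

| parameter | unit | default | rationale |
|---|---|---|---|
| `b` (decay_length) | bp | 1000 | in vivo propagation distances measured with independent protocols, in both prokaryotes and eukaryotes, consistently fall near 1 kb |
| `alpha` | 1/(rate·bp) | 3×10⁻⁵ | calibration constant of the arbitrary expression unit: a 1-kb gene at unit rate yields `sigma_a = 0.03`, inside the experimentally observed local range |
| `sigma0` | – | 0.0 | free eukaryotic DNA is torsionally relaxed on average; prokaryote-like settings use ≈ −0.06 |

Inside the gene body the field is linearly interpolated between `−sigma_a`
at the TSS edge and `+sigma_a` at the 3′ edge. This branch only serves
plotting continuity: promoters of valid gene pairs never lie inside a
partner's transcription unit, and the coupling solver never consumes it.

## 2. Supercoiling-dependent promoter opening

The cost of forming the initiation bubble is computed with an equilibrium
stress-induced duplex destabilization (SIDD) calculation in the
**single-bubble approximation**: states are the closed duplex and all
contiguous denatured runs `(s, n)`. A run costs a nucleation penalty plus
per-base pairing energies, plus a torsional term obtained by *analytically*
minimizing, over the uniform residual twist of the open region, the sum of
open-region twist energy `(C/2)·n·tau²` and the quadratic residual
superhelicity energy `(K/2)·a_r²`, with `a_r = alpha_Lk + n/h − n·tau/2π`
and `alpha_Lk = sigma·N/h`:

    G_tor(n) = (K/2) · a² · C / (C + K·n/4π²),    a = alpha_Lk + n/h.

Boltzmann statistics give the probability `p_open` that a designated
initiation window is entirely inside the run; the opening free energy is
the log-odds `dG_open = −RT·ln[p/(1−p)]`, with the covering and
non-covering sums both accumulated in log space so neither tail of the
transition suffers `1−p` cancellation.

Energetic defaults (37 °C, all overridable): nucleation 10.8 kcal/mol,
pairing 0.26 (A·T) / 1.30 (G·C) kcal/mol/bp, `C` = 2.5 kcal/mol/rad²/bp,
`h` = 10.4 bp/turn, `K = 2200·RT/N` kcal/mol/turn². These are declared
package defaults of a desk-scale engine, not literature claims.

**Domain size.** `N` is the size of the closed topological domain carrying
`sigma`, an explicit parameter (`domain_size`, default 5000 bp,
plasmid-like) rather than the length of the analysed window. This is what
makes the computed `dG_open` insensitive to how much flanking sequence is
included (verified in the tests at machine precision); tying `N` to the
window length would couple the torsional energetics to an arbitrary
analysis choice.

**Known artifact.** In the saturated regime (`p_open` > 0.95) the
single-bubble approximation produces small commensuration wiggles
(≲ 10⁻² in probability) as the optimal bubble length sweeps past the
boundaries of an AT-rich island; the crossover itself is strictly
monotone. Downstream simulations never see this structure because they
consume only the fitted monotone sigmoid (next paragraph) — the same
reasoning by which the duplex's second destabilization at extreme positive
torsion is excluded from the fit.

**Sigmoid fit.** The melting profile is summarized by

    dG_open(sigma) = q + v·sigma + m · Λ((sigma − sigma_c)/w),

with `Λ` the standard logistic, `sigma_c` the destabilization threshold,
`w` the transition width and `m, v, q` amplitude/slope/offset. The
least-squares fit (scipy `curve_fit`) constrains `m, v ≥ 0` so the fitted
curve is monotone non-decreasing on the whole axis, and records the fitted
`sigma` range as the model's validity domain.

## 3. Thermodynamic transcription rate

The expression level is proportional to the initiation probability of a
bound/unbound equilibrium of the transcription machinery, with the opening
penalty as the only `sigma`-dependent term:

    dG_init(sigma) = dG_open(sigma) + dG_bind,
    k(sigma) = k_max · exp(−dG_init/(R·T_e)).

`T_e` is an *effective temperature* absorbing the non-thermal,
polymerase-assisted component of bubble formation; it is the rate law's
single adjustable parameter and is calibrated by linear regression of log
expression on `−dG_open(sigma)`. The unsaturated Boltzmann form is chosen
deliberately: it is the only form under which the supercoiling fold-change

    rho(sigma; sigma0) = exp(−[dG_open(sigma) − dG_open(sigma0)]/(R·T_e))

is *exactly* independent of `dG_bind` and `k_max`, so all coupling
predictions need no knowledge of binding energetics. The default
`T_e = 558 K` (1.8 × 310 K) is an explicit placeholder on the scale of the
physical temperature; every coupled-pair quantity in this package is a
ratio (`rho`) parameterized by `T_e`, never dependent on its absolute
default. Exponents are capped at ±500 with a warning to avoid overflow.

## 4. Coupled gene pairs

Each gene's promoter feels the basal density plus the partner-generated
perturbations (self-influence is excluded: a gene's own torsional lobes do
not act back on its own promoter — including them would produce
unconditional self-activation with no counterpart in the mechanism being
modeled). With the source amplitude re-evaluated from the current rates,
the stationary state is the fixed point of

    k_i = k0_i · rho_i( sigma0 + Σ_{j≠i} dsigma_{j→i}(k_j) ),

solved by damped synchronous iteration (damping 0.5, relative tolerance
10⁻⁸, ≤ 10 000 iterations) initialized at the rates in absence of local
supercoiling. The damped symmetric start makes the selected attractor
deterministic and exactly symmetric for symmetric constructions.

**Sigma clamping.** The solver clamps each promoter-local `sigma` iterate
to the opening model's fitted validity range (default [−0.15, 0.05]).
Outside that range the sigmoid is an uncontrolled extrapolation, and the
self-reinforcing divergent configuration (`v > 0`) would otherwise admit
no finite fixed point. Clamping bounds the map into a compact box, so a
fixed point exists; physically it encodes that a promoter's response
saturates once its initiation site is fully destabilized. The fold-change
and rate functions themselves are *not* clamped.

**Geometry.** `promoter_distance` is TSS-to-TSS between boundary TSS
coordinates (gene start on `+`, gene end on `−`); this keeps symmetric
constructions exactly symmetric and makes the convergent diagrams start at
`d = l₁ + l₂`. An intergenic-gap convention is available as a switch.

**Default simulation promoter.** The illustrative diagrams use a synthetic
"CMV-like" sigmoid (`sigma_c = −0.042`, `w = 0.01`, `m = 3`, `v = 2`,
`q = 2` kcal/mol): threshold and width in the range produced by the SIDD
engine on AT-rich promoter cores, and amplitude a few multiples of
`R·T_e` so that coupled fold-changes span the experimentally reported
few-fold range rather than switching between astronomically separated
states. With it the phase diagrams reproduce the expected structure:
divergent pairs mutually activate (strongest at relaxed, eukaryote-like
`sigma0`, with a sharp distance cutoff), convergent pairs mutually repress
(deepest at prokaryote-like `sigma0` ≈ −0.06), tandem pairs split into a
mildly activated upstream and a repressed downstream gene at intermediate
`sigma0`, and all coupling becomes negligible beyond ≈ 3 decay lengths
(≈ 3 kb).

## 5. Isolated-pair genomics

Candidate pairs are adjacent genes along a chromosome (genes overlapping
another gene are dropped first, with counts logged). A pair is accepted
when (i) each gene's transcription unit comes within 5 kb (nearest point)
of the partner's TSS and (ii) both TSSs lie more than 3 kb from every
other annotated transcription unit, non-coding genes included. The
"promoter" is operationalized as the annotated TSS point. Pair separation
defaults to the intergenic gap (TSS-to-TSS available), because gap-based
windows are the only convention under which convergent multi-kb gene pairs
can populate sub-3-kb bins.

Co-expression: two genes are correlated when they are jointly nonzero in
at least 6 of the experiments **and** their Pearson correlation over all
experiments (zeros included; zero-variance vectors fail the criterion)
exceeds 0.5. No multiple-testing control is applied — the criterion is a
fixed threshold, not a p-value procedure. Binned statistics per 200-bp
separation window report pair counts, correlated counts, the expressed
fraction over (gene, experiment) entries, and total/mean expression
(per-gene means; the identity total = 2 × count × mean holds exactly for
the two-member tables, and tandem members are tabulated separately).

## 6. Synthetic data: what it emulates, and what not

`make_genome` plants pairs of known orientation, separation and isolation
status in well-separated blocks, so the selection truth table is exact by
construction: spoiled pairs receive a background gene within 3 kb of one
TSS (spoiled non-divergent pairs are capped at 1.5-kb gaps so the
incidental spoiler-member pair provably fails isolation too).
`make_expression` draws log-normal basal levels (default 24 experiments,
emulating a multi-cell-line design), applies Bernoulli dropout per
(gene, experiment) to control the expressed fraction, multiplies isolated
pair members by the coupling model's fold-changes, and gives designated
correlated pairs a shared latent factor (and a shared dropout mask), by
default only below 1 kb of separation and preferentially in divergent
pairs — the gross structure of the real co-expression signal.
`make_promoters` emits random sequences with an AT-rich core emulating
thermodynamically unstable promoters. All generators are pure functions of
(spec, seed).

Not emulated: RNA-Seq count noise (negative-binomial overdispersion),
isoform-level TSS structure, chromatin-domain correlation, transcription
bursts. Passing pipeline tests therefore demonstrate the *selection and
statistics machinery* and the *model-driven orientation signatures*, not
that real data will show them with the same effect sizes.

## 7. Problem sizes and numerical choices

Tests and the acceptance script run the melting engine on ≤ 500-bp
sequences with bubbles ≤ 250 bp (the engine is O(L·n_max) per sigma after
log-space preaggregation), exhaustive-oracle comparisons on ≤ 40-bp
sequences, coupled-pair oracles on ~20 randomized configurations with a
4001-point scan + bisection, 50×50 phase diagrams, and 100-seed ensembles
of 80-gene uniform genomes — sizes chosen so the full validation cycle
completes in seconds while every claim is still exercised end to end.
Ties and degenerate inputs: zero-rate genes stay silent and neutral;
zero-variance expression vectors are "not correlated"; empty grids,
overlapping geometries, inverted coordinates, duplicate gene ids and
non-ACGT characters raise typed errors.

## 8. Known limitations

- Single-bubble SIDD: no multi-run states, no B–Z/cruciform/G-quadruplex
  competition, no salt-dependence fitting.
- Mean-field, time-averaged torsion: no stress waves, no polymerase
  collisions on convergent genes, no burst dynamics.
- The rate law's `T_e` must be calibrated per system; absolute rates are
  only defined up to `k_max·exp(−dG_bind/RT_e)`.
- N-gene chains are solved by the same fixed-point machinery, but chain
  phenomenology (collective transitions in dense genomes) is deliberately
  out of scope.
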