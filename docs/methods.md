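# Methods

This note documents the models implemented in `hairpinrep`, the parameter
choices behind them, and what the synthetic data can and cannot stand in for.

## Duplex thermodynamics (`hairpinrep.thermo`)

Free energies of short duplexes are nearest-neighbor sums over the unified
oligonucleotide parameter set, taken from Biopython
(`Bio.SeqUtils.MeltingTemp.DNA_NN3`), with internal mismatches from
`DNA_IMM1` and terminal mismatches from `DNA_TMM1`. The summation follows the
same conventions as Biopython's `Tm_NN` (terminal-mismatch parameters consume
the end step; initiation and terminal A·T/G·C penalties from the top strand),
so `Tm_NN` serves as an independent cross-check in the test suite while ΔH
and ΔS remain individually accessible here.

Steps in which **both** bases of a doublet are mismatched (tandem mismatches)
have no published unified parameters; they contribute zero ΔH/ΔS, i.e. the
step is treated as an unstacked internal loop. This errs toward destabilizing
such mutants, which is conservative for the tolerance criterion (a tandem
mutant counted as "rejected" would be rejected under any reasonable penalty).

**Salt correction.** The replication buffer is 150 mM NaCl + 20 mM MgCl₂.
Magnesium is folded into a sodium-equivalent, [Na⁺]eq = [Na⁺] + 120·√[Mg²⁺]
(von Ahsen), and the entropy is corrected by 0.368·(N−1)·ln[Na⁺]eq
(SantaLucia) — Biopython's `salt_correction` method 5, selectable through
`IonicConditions.salt_method`. Default strand concentration is 400 nM total
per complementary pair (two strands at 200 nM each).

**Two-state melting.** Tm = 1000·ΔH/(ΔS + R ln(C_T/4)) − 273.15 for
non-self-complementary duplexes at equal strand concentrations; the unbound
fraction solves the bimolecular mass-action equilibrium exactly (stable
quadratic root; the association constant is clipped at e^±60 to avoid
overflow far from the transition, where the fraction is 0 or 1 to machine
precision anyway).

With these choices the bit-0 information-domain duplex gives
ΔG(37 °C) = −14.4 kcal/mol and Tm = 50.6 °C, and the backbone junction
duplexes of the packaged library fall at 79.9–87.9 °C. The corresponding
measured values (−15.4 kcal/mol, 48 °C, 76–79 °C) sit 1–5 °C below the model
throughout — the familiar offset between NN predictions and dye- or
absorbance-based melting curves. All design-rule conclusions depend only on
the *ordering* Tm(info) < T_peak(67) < 74 < Tm(backbone), which is robust to
this offset, and quantitative targets carry tolerances that absorb it
(±1.5 kcal/mol on the duplex ΔG, ±3 °C on the info Tm).

**Melting-curve fitting** models the raw signal as
`lower(T)·(1−f) + upper(T)·f` with linear baselines and the two-state
unbound fraction f(T; ΔH, ΔS), fitted by least squares from four ΔH starting
values (−50…−160 kcal/mol) with baseline inits from the curve ends. Flat
data (relative range < 10⁻³) raise a no-transition error rather than
returning a degenerate fit.

## Strand library (`hairpinrep.sequences`)

The 16-strand library ships as a FASTA fixture (antisense ids carry a
trailing `*`). Information domains are *discovered*, not declared: for each
bit, the unique 15-mer common to all four sense strands whose reverse
complement occurs in all four antisense strands. Annotation splits each
strand into 5′ hairpin / info / 3′ hairpin around the exact-match location;
coordinates are 0-based half-open, and the hairpin spans (30–37 nt) absorb
the few bases the design leaves between stem-loop and info domain.

Backbone validation pairs the 3′ hairpin of each strand with the 5′ hairpin
of its successor *within its pool*: sense strands succeed A→B→C→D→A, while
the printed antisense sequences pair in the reverse order (A*→D*→C*→B*), a
consequence of the antiparallel assembly geometry. The longest complementary
stretch is found by a sliding-window scan tolerating up to 3 designed stem
mismatches (configurable); every junction of the packaged library pairs over
30–32 nt with ≤1 mismatch.

## Sequence space (`hairpinrep.seqspace`)

Mutants are enumerated in the complement strand only (the template strand is
the reference), exactly k substitutions per mutant, in a deterministic order
(position tuples lexicographic, bases alphabetical) so cached distributions
are byte-reproducible. The tolerance criterion is applied in its free-energy
form, ΔG ≥ −12.5 kcal/mol at 37 °C — the threshold equivalent to a 10 °C
drop in info-domain melting temperature. "Exactly k" is the default reading
of the k-mutation neighborhood; a pooled ≤k variant is available
(`tolerance_fraction(..., exactly=False)`) and can only report a lower
fraction, since the k=1,2 mutants bind more strongly. Terminal positions are
indices 0 and 14 of the 15-mer.

## Growth kinetics (`hairpinrep.kinetics`)

Time is continuous in cycle units; data are sampled at integer cycles. The
closed form is evaluated in sum/difference coordinates; for k < 10⁻⁹ the
k→0 limit is used directly to avoid cancellation in 2k0/k. A numerical
integrator (`solve_ivp` at rtol 10⁻¹⁰) provides the independent oracle in
tests.

Joint (k, k0) fits run bounded nonlinear least squares from a 4×3 grid of
starting values and keep the best optimum; points above 50% of the
per-strand total concentration (configurable) are excluded because the model
has no saturation. Uncertainties come from a seeded bootstrap that resamples
time points within each trace — trace-level resampling would collapse to
zero-width intervals for single-trace fits, hiding the weak identifiability
of k when no template series is available.

Serial transfer alternates closed-form growth segments with multiplicative
dilution of both species; samples at transfer cycles are the pre-dilution
values (the sawtooth peaks). The no-monomer control disables growth
entirely, and its observable is the diluting template pool, since no product
can form. The dilution-factor fit is a bounded 1-D least squares on (0, 1]
with (k, k0) frozen.

The sedimentation endpoint fit is a 3-parameter logistic on the
first-frame-normalized trace, `1 + a/(1 + e^{−r(t−t0)})`; `a` is the
relative concentration increase and flat series return amplitude 0 with a
flag instead of an error.

## Per-cycle simulator (`hairpinrep.cyclesim`)

One thermal oscillation is one discrete step with stage probabilities:

- `p_bind(T_base)` — info-domain occupancy, 1 − unbound fraction of the info
  duplex (0.85 at 45 °C);
- `p_zip(T_base)` — per-junction backbone closure during the base hold,
  1 − exp(−ζ·f_open(T)·t_hold), where f_open is the unimolecular open
  fraction of a hairpin stem;
- `p_release(T_peak)` — replicate/template separation, the info-duplex
  unbound fraction at the peak (0.9993 at 67 °C);
- `p_destroy(T_peak)` — complex loss per peak. An assembled tetramer
  survives only if **all four** backbone junctions stay bound, each with its
  own computed duplex thermodynamics: with the info duplexes molten at the
  peak, any open junction exposes free ends and the complex is treated as
  dismantled. This joint-survival form, rather than a single representative
  duplex, is what produces the observed sharp collapse of amplification just
  below the backbone melting range;
- `r_spont(T_base)` — untemplated formation, ∝ f_open², since two free
  hairpins must fluctuate open simultaneously to nucleate.

The hairpin stem stability is not derivable from the strand sequences
without a folding model (out of scope), so it is a parameter: ΔH = −60
kcal/mol with a 62 °C unimolecular midpoint, placing stem fluctuations
between the info-domain and backbone transitions. It gives f_open = 0.0015
at 39 °C vs 0.008 at 45 °C — hairpins locked shut at 39 °C, reproducing the
slow templating there — and a ~27× spontaneous-rate increase from 45 to
51 °C.

Two free parameters are calibrated once against the fitted growth constants
under the reference protocol: ζ so the ideal per-cycle gain
p_bind⁴·p_zip⁴·p_release equals k = 0.16 cycle⁻¹, and the spontaneous
prefactor so r_spont(45 °C) = k0 = 0.4 nM·cycle⁻¹.

The deterministic step integrates the resulting effective linear system over
one cycle with the exact propagator (matrix exponential), not a forward-Euler
map: the 20-minute base hold is long against hybridization timescales, and
the exact propagator makes the ideal limit (full occupancy, complete
release, no destruction, no depletion) reduce to the closed-form growth
model to machine precision — the simulator's primary correctness anchor.

Monomer depletion scales all production by the scarcest required strand and
is what bounds product mechanistically (saturation emerges rather than being
imposed). When a matching strand is knocked out, the wrong-bit strand at
that position incorporates at a reduced relative occupancy (default 0.4,
anchored to the measured ~40% single-defect endpoint yield); incomplete
assemblies go to a 3:4-type partial pool (three strands, two junctions
closed on the circular template). Destroyed complexes return their strands
to the monomer pool, credited to the strands the current cycle incorporates;
this bookkeeping is exact when no strand is knocked out (mass conservation
is tested to 0.1%) and approximate for pools mixing strand provenance.

The stochastic variant draws Poisson copies of every production term and
binomial survival of every destruction/release term at a configurable
molecules-per-nM scale (default 1000); its per-cycle map is linear in the
state, so the ensemble mean tracks the deterministic run up to
discretization (tested at 1000 seeded runs within two standard errors).

## Synthetic data (`hairpinrep.synth`)

The gel-quantified and plate-reader observables behind this analysis are not
deposited, so seeded generators emulate their statistical structure:
closed-form growth traces, serial-transfer traces with the fading control,
two-state melting signals through linear baselines, endpoint-yield tables
for the knockout patterns, and random-sequence pools as negative controls.
Noise is multiplicative Gaussian (σ_rel = 0.10) plus a 1 nM additive floor —
band-intensity quantification scales with the band, with a detection limit.
Every generator is a pure function of (parameters, seed).

What passing tests show — and what they do not: parameter-recovery tests
demonstrate that the estimators are consistent and correctly scaled *under
this noise model*; they cannot validate the noise model itself against real
gels, nor the absolute magnitudes of gel-derived time courses or
sedimentation traces, which only the property suites (orderings, reductions,
conservation laws) constrain. The endpoint-yield generator's defaults are
the measured means (37 nM full, 14 nM single defect) with the double-defect
mean set by the independence arithmetic 37·0.4², and the "+−+−" pattern
defaulting to the same double-defect mean.

## Numerical and interface conventions

Temperatures in °C at interfaces, Kelvin internally; energies kcal/mol,
entropies cal/(mol·K); concentrations nM in kinetics and the simulator,
molar inside thermodynamic equilibria. Problem sizes used by the shipped
analyses: full mutant enumeration to k = 3 (12,285 duplexes, seconds);
kinetic recovery on 20 replicate families of five 6-cycle traces; 1000-run
stochastic ensembles for the simulator consistency check. Fits are
deterministic given the seed; bisection inversions terminate at 10⁻⁶.

## Known limitations

- No unimolecular folding model: hairpin stability is a parameter, not a
  prediction, and partition-function effects (partial zipping, bulges) are
  outside the two-state treatment.
- The simulator coarse-grains each cycle to expected-value (or
  Poisson/binomial) transitions; it does not resolve within-hold kinetics,
  and partial complexes neither complete nor template in later cycles.
- Mutant sequence space covers substitutions in the complement strand only;
  insertions/deletions and template-strand mutations are out of scope.
- Agglomeration, sedimentation physics and convection are not modeled; only
  the endpoint logistic fit of sedimentation traces is provided.
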