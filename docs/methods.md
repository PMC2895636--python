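# Methods

## The model

`condcorr` simulates a single-compartment conductance-based neuron of the
kind used for generic stomatogastric ganglion (STG) cells.  The membrane
carries eight currents — fast Na⁺ (g_Na), fast and slow transient Ca²⁺
(g_CaT, g_CaS), fast transient K⁺ (g_A), Ca²⁺-dependent K⁺ (g_KCa),
delayed-rectifier K⁺ (g_Kd), the hyperpolarization-activated mixed-ion
inward current (g_H), and an ohmic leak — each of the Hodgkin–Huxley form

    I = ḡ · m^p · h^q · (V − E),      τ_m(V) dm/dt = m_∞(V) − m,

with the Ca²⁺-dependent K⁺ activation carrying an additional Ca/(Ca+3 µM)
factor.  An intracellular calcium pool relaxes with τ = 200 ms toward a
level set by the instantaneous calcium current
(τ dCa/dt = −14.96 µM/nA · I_Ca − Ca + 0.05 µM), and the calcium reversal is
recomputed every step from the Nernst relation with 3 mM external calcium
(RT/2F = 12.199 mV at 10 °C).  All kinetics live in a structured YAML file
(`src/condcorr/data/stg_kinetics.yaml`), not in code: each curve is one of
five parametric forms (logistic, calcium-scaled logistic, offset sigmoid,
double-exponential, product of sigmoids), so the integrator is
model-agnostic and the numeric transcription is auditable.  The file carries
a `status: transcribed` marker: these tables come from the published
STG-model lineage (cultured stomatogastric cells; the H current from
thalamic relay neurons) and have not been re-derived here.

Maximal conductances sit on an 8-dimensional grid of equidistant levels from
zero to a physiologically relevant per-channel maximum (Na 500, CaT 12.5,
CaS 10, A 50, KCa 25, Kd 125, H 0.05, leak 0.05 mS/cm²).  The full study
grid uses 6 levels (6⁸ = 1,679,616 models); any coarser sub-grid over the
same ranges is available for desk-scale work.

## Integration

The integrator is exponential Euler — exact relaxation of each gating
variable toward its tabulated steady state over one step, and an exponential
update of V using the instantaneous total conductance — which is the de
facto standard for this model family and is exact for the passive membrane
(the passive-relaxation test demands ~1e-9 mV agreement with the RC closed
form).  Defaults: dt = 0.05 ms, 10 s total with the first 4 s discarded as
transient, V₀ = −50 mV, gates at steady state for V₀, calcium at rest.
These are package choices (the reference analysis does not report them); the dt-halving
test checks that activity class and burst/spike metrics of random grid
models move by <5% under dt → dt/2.  Gating curves are pre-sampled on a
0.01 mV table over −120…+60 mV and linearly interpolated; outside that range
the tables clamp, which prevents exponential overflow for extreme parameter
sets.  Calcium is floored at 1e-4 µM.  Grid runs are embarrassingly parallel
by record, deterministic per record, resumable from TSV chunk checkpoints
(a malformed checkpoint is a hard error), and chunking-invariant.

## Activity classification

From each trace (after transient discard) the classifier finds all strict
voltage maxima (plateau crests count once); maxima above the spike threshold
(−30 mV, strict) are spikes, the rest are sub-threshold activity.  The
taxonomy:

* **silent** — no maxima, or no supra-threshold spikes;
* **periodic vs irregular** — every inter-event interval within 1%
  (inclusive) of the mean interval; for spikers the rule is applied to
  inter-maximum intervals, for bursters to burst-start intervals (the
  source states the 1% rule only for maxima; mirroring it onto burst starts
  is the least-surprising extension);
* **bursting** — inter-spike intervals within 30% (inclusive) of the
  per-trace maximum interval are inter-burst intervals; bursts are the
  maximal spike runs between them.

Two rules the taxonomy needs are genuinely underdetermined and are package
decisions, chosen once and fixed:

* *Irregular spiking vs irregular bursting.*  A segmented train counts as
  bursting only when intra- and inter-burst intervals separate in time
  scale: max intra-burst ISI ≤ 0.5 × min inter-burst interval, and at least
  two bursts.  Without this, any jittered tonic train whose longest ISI
  exceeds the shortest by >30% would be called bursting.
* *All intervals qualify as inter-burst* (every "burst" has one spike).
  Such a trace is **one-spike bursting** when sub-threshold maxima (a slow
  wave) exist between spikes, otherwise tonic spiking — reserving the
  one-spike class for traces with genuine sub-threshold oscillation
  structure rather than labelling every tonic spiker a burster.

Metrics: spike frequency = 1000/mean ISI; burst period between consecutive
burst starts; burst duration first-to-last spike (0 for one-spike bursts,
hence duty cycle 0); duty cycle = mean duration / mean period.  The
slow-wave peak is approximated by the last maximum belonging to a burst
(the last maximum before the following inter-burst minimum — this includes
trailing sub-threshold maxima, which is what makes the approximation
meaningful); slow-wave amplitude is that peak minus the between-burst
minimum.  Rise-phase slopes: point 1 is the inter-burst minimum, point 5
the next upward −30 mV crossing (linearly interpolated), points 2–4 cut the
span into four equal time sections; average slope = (V₄−V₁)/(t₄−t₁)
(dropping the 4→5 section to avoid the first-spike upstroke), initial =
1→2, central = 2→4, averaged over bursts.  Traces with fewer than three
maxima but at least one spike are flagged `unclassifiable` rather than
silently dropped.  All thresholds are configuration entries whose defaults
are the reference-analysis values.

## Populations

Single-metric populations use left-closed right-open bins, open at both
extremes (a model at duty cycle exactly 0.05 falls in the upper bin).
Paper-mode edges: spike frequency {10, 25, 50, 75} Hz; duty cycle
{0.05, 0.1, 0.2, 0.4, 0.6}.  Multi-criteria ("pacemaker") populations are
conjunctions of closed ranges; adding a criterion can never grow a
population.

The full-scale screen covered 47 sub-populations, but their exact
enumeration is not itemized in the reference analysis.  The reference-mode reconstruction
here is: 6 activity-class groups + 5 frequency groups + 6 duty-cycle groups
+ 3 rise-slope schemes × 6 groups + 5 single pacemaker criteria + 7
criterion combinations = 47.  The slope-scheme edges, the pacemaker ranges
other than slow-wave amplitude 10–30 mV, and the combination list are
reconstructions (marked `reconstructed` in `reference_config()`); the
source itself reports that shifting the arbitrary boundaries did not
drastically change the correlations found.  Spike-height and
spikes-per-burst schemes are implemented but off by default (they lowered
the overall success rate in the original analysis).

## Correlation screening

For each population and each of the C(8,2) = 28 conductance pairs, models
are binned by grid level into a 2-D histogram (the other six conductances
marginalized).  A pair is a correlation when both cutoffs pass (strict
inequalities):

* raw chi-squared independence statistic > 500, with expected counts from
  the row/column marginals and zero-marginal rows/columns dropped (their
  expectation is undefined; dropping is the contingency-table convention);
* Spearman |ρ| > 0.2, computed with midranks (ties are pervasive on a
  6-level grid; ρ on grid levels equals ρ on conductance values because the
  level→value map is strictly monotone).

The raw statistic is deliberately not scaled by N: on a sparsely sampled
grid, a dependence seen in a large population should clear the bar more
easily than the same pattern in a tiny one.  Consequently chi-squared
scales linearly with population size, and correlation counts from
desk-scale grids are not comparable to full-scale tallies.  A constant
conductance margin makes ρ undefined; such pairs simply fail the criterion.
Populations below a configurable floor are scanned with a warning.

The independence matrix (outer product of normalized 1-D marginals × N) and
the difference matrix (100·(O−E)/N, summing to zero) support the visual
check for false positives.  The original study's curation was manual; here
an edge-concentration heuristic (fraction of the population at level zero
of either axis, default threshold 0.5) *flags* suspect correlations into a
review table — nothing is silently excluded, and the package asserts no
false-positive count of its own.

## Correlation-based populations and enrichment

The mask of a correlation is the set of grid cells of its conductance plot
holding ≥ 3% (inclusive) of the source population.  The correlation-based
population cb_i is every model of the whole database — activity type
ignored — whose pair levels fall inside the mask; multiple masks combine by
conjunction (intersection).  Enrichment of target type i:

    %Success_cb = 100·N(cb_i ∩ type_i)/N(cb_i),
    %Success_orig = 100·N(type_i)/N(database),
    f_Success = %Success_cb / %Success_orig.

Controls: (a) random masks on random pairs, matched to the correlation
mask's cell count — the minimal fair control given that only the mask
footprint is specified; the choice is recorded in output metadata; (b) ideal
diagonal-band masks of configurable width and sign on random pairs.  On a
database whose conductances are independent of the type label, both have
expected f_Success = 1; the full-database mask gives f_Success = 1 exactly.

## Synthetic data

* **Trace fixtures** are piecewise-linear waveforms, not ODE output, so
  classifier tests are exact up to sampling: spike peaks, troughs and
  threshold crossings are snapped to the sampling grid, and every
  construction parameter (class, frequency, burst period/duration, spikes
  per burst, slow-wave peak, one- or two-segment rise slopes, interval
  jitter for irregular classes) is recovered by the classifier within one
  sampling interval's quantization.  The fixture family spans all six
  classes with 104 specs.  What these fixtures do **not** emulate: spike
  shape, intra-burst frequency adaptation, noise, or any dynamics between
  the constructed landmarks — passing them shows the metric definitions are
  implemented correctly, not that the classifier is robust to arbitrary
  real traces (the reduced-grid end-to-end runs cover ODE output).
* **Planted databases** draw each model's grid point uniformly and
  independently, except that for a planted (pair, sign, width, adherence)
  a model of the planted type lands, with probability = adherence,
  uniformly inside the diagonal (or anti-diagonal) band of that pair's
  grid.  This is the minimal generator matching the near-linear band
  structure the miner targets; unplanted marginals stay uniform within
  binomial tolerance.  The standard operating point for recovery studies is
  adherence 0.8, width 1, n = 50,000 — at it the miner recovers the planted
  pair with the correct sign in every tested seed and flags no unplanted
  pair.  Planted databases carry no trace-level metrics (NaN), so only
  class-level populations apply to them.
* **Reduced grids** re-run the real model on 2–3 equidistant levels per
  conductance over the full ranges (256 / 6,561 models).  Problem sizes
  throughout — the 3-level analysis grid, 20–40 seeds for recovery studies,
  200 seeds for enrichment nulls, 30,000–50,000-model surrogates — are the
  package's desk-scale choices; the full 6⁸ grid is supported (checkpointed
  `run_grid`, supplementary-dump loader) but not exercised by the test
  suite.

## Numerical and degenerate-input choices

* "Within 1%" and "within 30%" are inclusive (≤ / ≥); the correlation
  cutoffs χ² > 500 and |ρ| > 0.2 and the spike threshold "> −30 mV" are
  strict, matching how each rule is stated.
* Bins are left-closed right-open everywhere; criteria ranges are closed.
* An empty histogram makes χ² an error, not zero; an empty mask is refused
  by cb-population selection; an empty cb population makes %Success an
  error.  Divergent integrations are reported with the grid index and time
  of failure, and recorded as `unclassifiable` in grid runs.
* All randomness (surrogate draws, control masks, fixture jitter) flows
  from explicit seeds; every store writes provenance (grid definition,
  kinetics name, simulation config) in a JSON sidecar.

## Known limitations

* The kinetics/grid transcription has not been independently re-derived
  here; the YAML `status` field exists so a corrected transcription can be
  dropped in and databases record which kinetics built them.
* The 47-population enumeration and the pacemaker ranges beyond SWA
  10–30 mV are reconstructions (above).
* The screen is 2-D by design: dependencies among three or more
  conductances are only detected insofar as they shadow onto pairs.
* Visual curation is approximated by a transparent heuristic flag; the
  package reports its flags without asserting the original manual counts.
* No synapses, neuromodulation, current-injection protocols, temperature
  dependence, or stochastic channels.
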