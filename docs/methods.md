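# Methods

## Problem setting

`loophub` analyses parallel spike trains recorded simultaneously from many
brain areas (e.g. multi-probe Neuropixels sessions) and asks two questions:

1. Which groups of two or three neurons form *cell assemblies* — recurring
   joint activity patterns at some temporal resolution and inter-neuron
   delay — and how do those assemblies distribute across area pairs?
2. Are neurons embedded in *loop-like* triplets (delayed chains
   Area_i → Area_j → Area_i, the minimal re-entrant motif between two
   regions) preferentially the *hub* neurons that coordinate with many
   external areas?

Every stage is exercised end-to-end on synthetic recordings with planted
ground truth, so the statistical machinery can be validated without any
external dataset.

## Assembly detection

### Binning and the coincidence statistic

Spike trains are binned on a half-open grid (`[t, t+b)`; a spike on an edge
belongs to the bin starting there; a trailing partial bin is dropped) and
binarized. For a neuron pair and a lag `l`, the joint count `J(l)` is the
number of bins in which both neurons are active after shifting the second
train by `l` bins; bins without a counterpart after the shift are dropped
from both series. The search grid pairs bin sizes
`[0.01 … 0.1] s` with maximum lags `[19 … 1]` bins, spanning coordination
precision from 10 to 100 ms and delays up to ±200 ms. Within one bin size
the lag maximising `J` is the candidate (ties: smaller |lag|, then the
negative lag).

### Null model

The null conditions on per-chunk activity margins. The series is cut into
non-overlapping chunks of `chunk_bins` bins (default 100; a trailing short
chunk is kept, and a series shorter than one chunk is a single chunk).
Within a chunk, given the two neurons' active-bin counts, the overlap of two
fixed-size random subsets of bins is hypergeometric; the total null count is
the sum of independent per-chunk overlaps. Conditioning on per-chunk margins
is what buys tolerance to slow non-stationarity: a rate drift moves the
margins, and the null moves with them, so only *within-chunk* coordination
registers as signal.

The exact first three cumulants of that sum are accumulated per chunk (the
hypergeometric third central moment factorises over the two margins, so all
three cumulants are inner products over chunks) and the upper-tail p-value
comes from a shifted gamma matched to those cumulants, with a 0.5 continuity
correction, falling back to a normal tail when the skew vanishes. A plain
normal tail is measurably anti-conservative here: for sparse trains the
per-chunk overlaps are strongly right-skewed, and selecting the best of
~140 grid configurations amplifies the tail error (measured false-positive
fraction 0.060 at α = 0.05 with the normal tail, 0.045 with the gamma
tail). The approximation is validated two ways: against the exact
single-chunk hypergeometric tail, and against a within-chunk permutation
surrogate (`surrogate_null_p`, p = (1 + #{J_surr ≥ J_obs})/(n+1)), which
realises exactly the conditioned null; median |Δp| over 200 moderate-signal
cases is ~0.007.

### Multiple comparisons and resolution selection

All (bin size, lag) p-values of one candidate pair form one family and are
Holm-corrected together (the step-down adjustment is computed directly in
numpy; it is verified identical to statsmodels). Across bin sizes the
candidate with the smallest adjusted p is selected; raw joint counts are not
compared across resolutions because a coarser bin trivially accumulates more
coincidences, which would make every assembly collapse onto the coarsest
grid entry. A pair is significant when its best adjusted p < α (default
0.05). Cross-pair multiplicity is deliberately *not* corrected: α is the
per-pair budget, so on pure-noise recordings the expected fraction of
significant pairs is at most α — this is the detector's calibration
property, checked by simulation.

### Agglomerative triplet extension

Each significant pair's activation train (the bins where the complete pair
pattern occurs, indexed in the lag-0 member's frame) is treated as a unit
and tested against every remaining neuron at the pair's bin size over its
full lag range. The (candidate × lag) p-values form the assembly's family,
Holm-corrected; the most significant candidate below α joins, lags are
re-referenced to the earliest member, and identical member sets reached from
different seed pairs collapse onto the most significant configuration.
Assemblies stop at three members: the motif taxonomy concerns pairs and
triplets, and the combinatorial cost of larger patterns grows steeply.

One behaviour worth knowing: the extension null conditions only on margins,
not on the pair substructure. A marginally significant pair that shares a
member with a strong assembly can therefore extend into a "significant"
triplet by riding the strong pair's correlation. These extras do not affect
recovery of planted structures and are an inherent property of agglomerative
coincidence testing; downstream statistics operate on the detected sets.

## Motif taxonomy

Pairs: intra- vs inter-regional (member areas equal or not) ×
synchronous (all lags zero) vs directional (leading = lag-0 member).
Triplets spanning exactly two areas with *all* consecutive lags strictly
positive and the first and last member in the same area are loop-like; the
same object is a *direct* loop w.r.t. its outer area and a *reverse* loop
w.r.t. its inner area. Everything else is non-loop-like with an explicit
subtype: `contains_synchrony`, `unidirectional_chain`, `intra_regional`
(one area), `three_area`. Any zero-lag link disqualifies a loop because the
motif is defined by a delayed chain; synchrony belongs to the non-loop
class.

Neuron populations: `loop_like` = member of ≥1 loop-like triplet (dominates);
`non_loop_like` = member of ≥1 two-area non-loop triplet and no loop-like
one; `other` = neither. One-area and three-area triplets are excluded from
the control population by default (the loop/non-loop contrast concerns
two-area triplets; both compared populations should count external areas
without bias); `include_intra_regional` re-admits one-area triplets for
sensitivity analyses.

## Area-pair probabilities

All probabilities are pooled empirical proportions: detected assemblies of a
kind divided by the number of *possible* neuron combinations of that kind,

- inter-regional pairs: `n_i · n_j`;
- intra-regional pairs: `C(n_i, 2)`;
- two-area triplets: `C(n_i,2)·n_j + C(n_j,2)·n_i = n_i·n_j·(n_i+n_j−2)/2`;
- fixed-direction loops (outer area i): `C(n_i,2)·n_j`.

For areas recorded in several sessions, counts and denominators are summed
across sessions *before* dividing — a pooled ratio, never a mean of
per-session ratios (the two differ whenever denominators differ). Normalised
directional differences are `(P_ij − P_ji)/(P_ij + P_ji)`; the
Int-Ext index is `P_ext/(P_ext + P_int)`, 0.5 meaning equal propensity.
Quantities with zero denominators (or a 0/0 index) are undefined and
propagate as an explicit `"X"` marker through all outputs rather than NaN,
so downstream tables distinguish "not estimable" from "estimated zero".
The loop probability conditioned on pair-forming neuron subsets is flagged
unreliable below a denominator floor (default 50 possible triplets): with
subsets of 2 and 3 neurons a single loop already yields 1/9 ≈ 0.11, a
number too coarse to rank.

## Directionality and latency tests

Directional pair asymmetry per area pair: exact two-sided binomial at
p₀ = 0.5 over the two directions, delayed pairs only (synchronous pairs are
excluded because their expected rate depends on the bin size in a way the
directional null does not). Loop-chain asymmetry: exact two-sided binomial
at p₀ = (n_i − 1)/(n_i + n_j − 2), the fraction of possible two-area
triplets whose repeated area is i; two-sidedness uses the
minimum-likelihood convention (scipy's `binomtest`), the standard exact
choice when p₀ ≠ 0.5. Sidedness is not stated for these tests in the
problem formulation; two-sided is the conservative reading for detecting
asymmetry in either direction. Chain-half latencies (lag difference × bin
size per link) are compared with a one-tailed pooled-variance two-sample t
test. Rankings sort area pairs by probability (descending) after filtering
to pairs with ≥100 neurons in each area and ≥2 mice; ties break by larger
possible-combination count, then lexicographically, so output order is
deterministic.

## Hubness and the embedded-hub test

External hubness = number of distinct external areas with ≥1 inter-regional
pair (multiplicity ignored); internal hubness = number of distinct same-area
partners. Two hub definitions are carried in parallel:

- **percentage**: score strictly greater than half the possible connections;
  areas where no neuron or every neuron passes are untestable under this
  method (hypo-/hyper-connectivity);
- **percentile**: score at or above the nearest-rank 95th percentile of the
  area's pooled score distribution, ties at the threshold included, zero
  scores never hubs. The reference distribution pools the two compared
  populations, which avoids biasing the threshold toward either group; the
  alternative (per-population thresholds) would make the 2×2 table
  degenerate by construction.

Per area, the 2×2 table (loop-like vs control population) × (hub vs
non-hub) is tested with one-tailed Fisher's exact (loop-like enriched),
with areas required to have ≥35 neurons in each population (about one third
of the 100-neuron ranking filter, as each population is one cell of a
three-way partition) and ≥2 mice. Benjamini–Hochberg FDR is applied across
the areas of one (method, scope, control) combination. Both control
definitions are supported: the non-loop-like population (unbiased external
area counting) and all remaining neurons.

## Synthetic data

Background activity: independent homogeneous or piecewise-constant Poisson
trains per neuron (piecewise rates exercise the chunked null's tolerance to
non-stationarity; the simplest violation of global stationarity). Planted
assemblies: `n_activations` occurrence times uniform over
`[t_start, t_end − lag_span − jitter]` (keeping member spikes in bounds);
member m fires at `occurrence + lags[m]·bin + U(0, jitter)` with jitter <
bin so the coordination is detectable at the planted resolution. Planted
spikes merge into the background; duplicate spikes in one bin are kept
(count-based binning handles multiplicity). All randomness flows from one
seed through spawned per-neuron streams, making scenarios bit-reproducible.

The **reference scenario** (recovery benchmark) uses two areas × 40 neurons,
600 s at 5 Hz, with 20 planted pairs (cycling inter-directional,
inter-synchronous and intra-regional structures) and 10 loop-like triplets
(alternating direct A–B–A and reverse B–A–B chains), 400 activations each,
bin 0.02 s, jitter 4 ms, all member sets disjoint. 400 coordinated events
against ~3 000 background spikes put each plant tens of null standard
deviations above chance — a strong-signal regime chosen to measure the
pipeline's bookkeeping (member sets, lags, motif classes), not its
borderline sensitivity.

The **hub-association scenario** works at the assembly level (no spike
simulation): a centre area with 100 loop-like and 100 control neurons split
across two mice, 8 external areas, each neuron pairing with each external
area independently with probability 0.15 (control) vs 3 × 0.15 = 0.45
(loop-like); enrichment 1 gives the matched null. These sizes give the
percentile-method Fisher test essentially full power at 3× enrichment while
the null rejection rate stays below the nominal α (Fisher is conservative
on discrete tables). Simulating at the assembly level is deliberate: the
quantity under test is the hubness/Fisher/FDR machinery, and spike-level
detection is already validated by the calibration and recovery benchmarks.

What the generator does **not** emulate: refractoriness, bursting,
oscillatory locking, behavioural covariates, electrode drift, spike-sorting
errors, or rate correlations between neurons. Passing recovery and
calibration therefore shows the statistics are implemented correctly and
calibrated for (piecewise-)Poisson backgrounds — not that the detector is
robust to every failure mode of real extracellular data.

## Numerical choices and degenerate inputs

- Lag sign: positive lag means the second train trails the first; assemblies
  store the leading neuron first with non-negative sorted lags.
- Lag ties: smaller |lag|, then the negative lag; resolution ties: larger
  joint count, then smaller bin size.
- Empty or all-silent trains: p = 1, joint count 0 (never an exception).
- Zero-variance nulls (degenerate margins): p = 1.
- A chunk of one bin contributes its mean but no variance.
- The >100-spike neuron filter is strict (exactly 100 spikes ⇒ removed) and
  counts spikes over the recording's declared `[t_start, t_end]`.
- Problem sizes in the validation suite (3 calibration recordings of 30
  neurons, 200 oracle-agreement cases, 100 + 100 hub seeds) are the
  package's benchmark defaults; they keep a full validation run in the
  minutes range on one core while leaving the measured margins (e.g.
  recovery 100% vs the 90%/80% thresholds) wide.

## Known limitations

- The detector is a reimplementation of the published CAD/CADopti *idea*
  with an explicitly documented null, not a bit-for-bit port; dataset-level
  percentages from the original MATLAB implementation will differ in
  detail.
- The activation-train extension inherits pair correlations (see above), so
  triplet counts on dense recordings are upper bounds on "genuinely
  three-way" structures.
- Areas recorded with very few neurons make loop denominators tiny; the
  conditional loop probability is flagged rather than suppressed.
- The percentile hub threshold is computed per pooled area, not per
  session; with strong per-session rate differences a session-stratified
  threshold could differ.
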