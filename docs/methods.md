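# Methods

`microcoh` estimates time–frequency connectivity between multichannel
electrophysiological signals at the temporal microscale (sub-second events
such as interictal epileptiform discharges), and summarises the result as
weighted networks, centrality profiles and group-level statistics. This note
documents the model, the numerical choices, and what the synthetic fixtures
do and do not establish.

## Ensemble imaginary wavelet coherency

### Continuous wavelet transform

Signals are decomposed with the analytic Morlet wavelet

    psi(t) = pi^(-1/4) * exp(i*omega0*t) * exp(-t^2/2),    omega0 = 6,

implemented in the frequency domain (daughter spectra sampled at the DFT
frequencies, zero-padded so the convolution is linear over the record, L2
scale normalisation). omega0 = 6 satisfies the admissibility condition to
numerical precision; the negative-frequency tail of the Gaussian is below
1e-7 and is truncated by the analytic (positive-frequency) construction.

Scales are dyadic with 12 voices per octave: `sigma_k = s0 * 2^(k/12)`,
`s0 = 2/fs` (two samples — the finest scale that is meaningful on the sample
grid). The admissible octave count for a record of duration `dt` is
`1 .. floor(log2(fs*dt)) - 1`; `build_scales` defaults to the maximum. The
equivalent Fourier frequency uses the centre-frequency convention
`f = omega0 / (2*pi*sigma)`. For fs = 500 Hz and 2 s records this spans
roughly 0.93–239 Hz over 97 scales.

### Coherency

For channels i, j observed over N event-locked epochs,

    rhat_ij(sigma, tau) =
        sum_n S( w_i^n * conj(w_j^n) )
        / sqrt( sum_n S(|w_i^n|^2) * sum_n S(|w_j^n|^2) ),

with S a time–scale smoothing operator (below). `|rhat|` (WTC) lies in
[0, 1] by the Cauchy–Schwarz inequality; `Imag(rhat)` (IWTC) is blind to
zero-lag coupling, because a common source reaching two sensors by volume
conduction arrives with zero phase difference and therefore contributes
only to the real part. Smoothing is applied per epoch before the ensemble
sum; because S is linear this equals smoothing the summed spectra, but the
per-epoch formulation keeps the single-trial (N = 1) estimator well defined.
Without any smoothing the single-trial coherence is identically 1 — the
numerator and denominator collapse to the same rank-one product — which is
why S is not optional. Zero-denominator bins are set to 0 and recorded in a
validity mask.

Phase convention: `arg(rhat_ij) = phi_i - phi_j`. A positive imaginary part
therefore means channel j leads channel i (information flow j -> i). On the
built-in cosine/sine demo pair this decodes as "y leads x", matching the
quarter-cycle lag of a sine behind a cosine.

### The smoothing operator S

S is the product of two unit-sum kernels, both truncated and renormalised
at the data edges (so constants pass unchanged and non-negative fields stay
non-negative):

* **time**: Gaussian of standard deviation `sigma` seconds at scale `sigma`
  (scale-proportional, so smoothing always spans a comparable number of
  oscillation cycles); implemented spectrally with a smoothed-ones
  normalisation field;
* **scale**: a 12-bin window (as many bins as voices per octave), with
  Gaussian weights of std 1 voice by default.

The Gaussian scale weighting (rather than a flat boxcar over the same 12
bins) is deliberate: a flat octave-wide boxcar gives every scale within
half an octave of a strong ridge essentially the full ridge cross-power,
flattening the coherence profile into a plateau whose maximum is then
decided by estimation noise — on the demo pair the apparent ridge moves
from 45 Hz to ~53 Hz. Decaying weights preserve the ridge curvature, and
peak extraction then localises to within one voice. The flat boxcar remains
available (`WaveletSpec(scale_kernel="boxcar")`), as does the kernel width
(`smooth_time_factor`, `scale_std_voices`).

A residual localisation limit remains and is worth knowing about: with any
scale-proportional time smoothing, averaging windows that sit close to the
edge of a rhythm's support are contaminated from outside it, more so at
larger scales. On the demo pair the sub-20 Hz ridge maximum lands half a
voice above 10 Hz (the 10.55 Hz grid scale) even in the noise-free limit.
Ridge frequencies should therefore be read at the grid's voice resolution
(about 6% per voice), not finer.

### Cone of influence

Bins closer than `sqrt(2)*sigma` seconds (the e-folding time of the Morlet
envelope, the operational "half wavelet length") to either record edge are
flagged invalid; the margin in samples is `round(sqrt(2)*sigma*fs)`. The
mask is symmetric and widens monotonically with scale. All downstream
aggregation (significance, network weights) is restricted to inside-COI
bins.

## Bootstrap significance

The null model is *independence between the two channels*, built from
user-selected background epochs rather than a parametric noise model: each
of B resamples draws `n_match` background epochs with replacement,
independently per channel (breaking any true cross-channel pairing), and
records the measure (`|IWTC|` by default, or WTC) per time–frequency bin.
The observed map is flagged where it exceeds the bin-wise q-quantile
(default q = 0.95) of the surrogate distribution, intersected with the COI.
Defaults: B = 300 (tests and examples use smaller B with pooled or bin-wise
thresholds as stated); quantiles pooled per scale are available for small B.
No multiple-testing correction is applied by default, matching common
practice for exploratory connectivity maps; the flag rate under the null is
therefore the per-bin rate 1-q, which the calibration tests verify to
within Monte-Carlo error.

## Networks

A **snapshot** averages `|IWTC|` over the bins of a closed time x frequency
window (inside the COI, and inside the significance mask when one is
supplied): the average is the edge weight, the mean sign of the IWTC is the
edge's direction score in [-1, 1], and pairs with no qualifying bin get no
edge. Edge magnitude uses `|IWTC|` because the imaginary part is the
volume-conduction-robust quantity of record; the signed mean is kept
separately so direction is never conflated with strength.

A **dynamic network** splits the record span T into `ceil(T/w)` windows of
width `w` (snapshot t covers `(t_min+(t-1)w, t_min+t*w]`; the first window
also takes the left endpoint; the last may be shorter and is flagged in
metadata). Windows partition the time bins exactly, so the full-window
quantities equal the bin-weighted means of the per-window ones.

**Global Microscale Connectivity (GMC)** is the mean edge weight over all
C(n,2) channel pairs with absent edges counted as zero — a density-sensitive
scalar comparable across subjects with different network sparsity (the mean
over existing edges only is available via a flag).

Layouts: force-directed (Fruchterman–Reingold, attraction proportional to
weight, seeded and unit-box normalised) for topology; a layered
(Sugiyama-style) hierarchy for directed flow — greedy cycle breaking
(repeatedly remove the weakest edge of a remaining cycle, reported as
feedback edges), longest-path layering, barycenter ordering. Crossing
minimisation is NP-hard; the layering is an explicit heuristic and should
be read alongside the force-directed view.

## Centrality

Ten weighted measures: degree (strength), harmonic closeness and
eigenvector centrality on the undirected view; in/out-degree, in/out
harmonic closeness, betweenness, HITS hubs and PageRank (damping 0.85) on
the directed view. Path-based measures use `distance = 1/weight`. Harmonic
closeness (normalised by n-1) is used so sparse or disconnected significant
networks stay well defined; eigenvector and hubs are normalised to unit
maximum; PageRank sums to 1. Direction scores orient edges (positive score:
the pair's second channel leads); near-ties (|score| <= 0.1 by default) are
treated as reciprocal.

**Dynamic centrality** evaluates one measure per snapshot of a dynamic
network (node x window series plus the per-window mean over nodes); empty
windows yield zeros.

**Characteristic centrality** ranks the measures themselves: the node x
measure matrix is z-scored per measure (the measures live on incommensurable
scales), decomposed by SVD, and the contribution of measure m to component
k is `100 * loading(m,k)^2 / sum_m loading(m,k)^2`. Measures are reported
sorted by contribution to PC1 together with per-component variance
fractions; constant columns are dropped with a warning.

## Group level

Subject snapshots over a common montage are stacked into `G` (subjects x
pairs, absent edges 0). The grand average is the columnwise mean. Network
modules come from PCA of the row-centred stack (each subject's own mean
connectivity subtracted — mean normalisation only, no variance scaling),
keeping `min(3, n-1)` components with variance fractions from the squared
singular values; loading signs are fixed (largest-magnitude entry positive)
so module maps are reproducible under subject reordering. The two-group
comparison reports Cohen's d with the pooled (n-1) standard deviation,
group A minus group B; Hedges' g is available via a flag.

## Synthetic data

`insilico_pair` produces the two-channel demo: channel x carries
`cos(2*pi*10 t)` on [0.5, 1.1) s and `cos(2*pi*45 t)` on [0.2, 1.4) s;
channel y the corresponding sines on [0.7, 1.2) and [0.5, 1.6); overlapping
gates add, so both rhythms coexist where their intervals intersect. Each
trial adds fresh white noise of standard deviation 0.05 per channel
(signal amplitude 1). Defaults: fs = 500 Hz, 2 s, 30 trials. The trial
count and sampling rate are package defaults chosen as typical event-locked
EEG practice; both are configurable.

`ied_network_sim` emulates event-locked recordings with known directed
coupling: independent 1/f background per channel (std 1), damped-oscillation
transients (default amplitude 8, decay 50 ms, 250 ms support — spike-like
bursts standing well above background) at each of the annotated events on
each coupling's source channel, copied to the destination channel with a
known lag and gain. A control mode places an independently jittered,
random-phase transient on every channel instead: event-locked power without
cross-channel lagged coupling. `background_epochs` supplies matched
white-noise epochs for the surrogate null.

What these fixtures do not emulate: real EEG spectra and artefacts,
volume-conduction mixing matrices, non-stationary background, electrode
geometry. Passing tests establish the estimator's internal correctness and
its behaviour under known ground truth, not clinical performance. In
particular the clinical group contrast (six focal-epilepsy patients,
intracranial recordings available only on request) is *not* reproduced; the
pipeline's group path is instead exercised on coupled-vs-uncoupled
synthetic cohorts, where the GMC contrast is large (Cohen's d well above 1)
by construction.

## Problem sizes used in tests

The test suite runs the full-resolution demo pair (97 scales x 1000
samples x 30 trials) once and reuses it across checks; calibration uses 20
replicates at fs 128 Hz, 4 octaves, B = 120; the cohort contrast runs 10
seeded cohorts of 2 x 10 subjects at fs 250 Hz, 3 channels, 12 events each.
These sizes were chosen to keep the whole suite in a few minutes while
leaving every Monte-Carlo check's error well below its asserted margin.

## Known limitations

* Ridge frequencies are meaningful at voice resolution only (~6%); see the
  smoothing discussion above.
* The surrogate null assumes the background epochs are representative of
  the channels' marginal dynamics; a background contaminated by genuine
  coupling weakens the test (unpaired resampling mitigates but cannot
  remove this).
* Direction scores reflect the sign of the imaginary coherency, i.e.
  quarter-cycle-like lags; in-phase or anti-phase coupling yields no
  direction.
* Heterogeneous per-channel sampling rates in EDF files are resolved by the
  reader's common grid rather than rejected.
* The layered layout is a heuristic; feedback edges depend on the greedy
  cycle-breaking order.
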