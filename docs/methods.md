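# Methods

`entronet` analyzes paired-condition resting-state studies at the level of
ROI time series: it builds binary functional networks at matched edge
density, measures the Shannon entropy of their degree distributions together
with standard integration metrics, compares each network against
degree-preserving random ensembles, and runs paired group statistics across
conditions. This note records the model, the conventions, and the design
choices a maintainer would want to know.

## Pipeline model

For each subject and condition the input is an `n_regions x n_volumes`
matrix of ROI-averaged signals with sampling interval TR (seconds). The
stages are:

1. **Optional nuisance regression.** Each region's series is replaced by its
   least-squares residual after projecting out user-supplied confound
   columns (motion parameters, tissue signals, global signal) plus an
   intercept. This stage operates at ROI level and is off by default: linear
   projection applied after ROI averaging is an acceptable approximation for
   synthetic data, and studies that regress confounds at voxel level should
   supply already-cleaned series.

2. **MODWT band-pass.** The maximum-overlap discrete wavelet transform
   (non-decimated, shift-invariant) splits each series into dyadic frequency
   bands; detail scale *j* occupies `[1/2^(j+1), 1/2^j]` of the sampling
   rate. The default is scale 3 with a Daubechies `db4` wavelet: at
   TR = 1.7 s this is ~0.037–0.074 Hz, the conventional resting-state band.
   The exact Daubechies order used in the wavelet-correlation fMRI
   literature varies; `db4` is the common default and the wavelet is
   configurable. Boundary handling is circular, which keeps the coefficient
   count equal to the series length, makes the transform exactly
   shift-equivariant, and preserves total energy across scales
   (`sum_j ||W_j||^2 + ||V_J||^2 = ||x||^2`); both properties are asserted
   in tests. The transform is computed by circular FFT convolution with the
   rescaled (`1/sqrt 2` per level) filters; filter coefficients come from
   PyWavelets.

3. **Gated correlation.** Pearson correlations between the scale-3
   coefficient series of every region pair, with a two-sided significance
   gate at `alpha = 0.05` from the t statistic with nominal `n_obs - 2`
   degrees of freedom. Entries failing the gate are zeroed and excluded from
   thresholding. The autocorrelation of wavelet coefficients makes the
   nominal test anti-conservative (the effective sample size of a band
   covering ~1/8 of the spectrum is roughly `n_obs / 8`); no correction is
   applied, the convention is recorded in the run manifest, and the gate's
   role here is edge-candidate screening rather than inference.

4. **Degree-matched thresholding.** Mean degree is a step function of the
   correlation threshold eta, so exact density matching across conditions is
   implemented by edge-rank selection: for target mean degree `<k>` on `N`
   nodes, the `L = round(<k> N / 2)` gated entries with the largest `|r|`
   become edges; ties at the cutoff break lexicographically by `(i, j)` so
   the edge count is exactly `L` and construction is deterministic. The
   reported eta is the smallest retained `|r|`. Networks built this way are
   nested across grid levels.

5. **Feasible degree grid.** The admissible window of mean degrees follows
   two criteria: at the minimum level every network must be connected and
   sparse (`<k> > 2 ln N`; for `N = 104` the bound is ~9.3, so the smallest
   admissible integer degree is 10), and at the maximum level every network
   must still be small-world relative to its degree-preserving ensemble
   (global efficiency below, local efficiency above the 30-member ensemble
   mean). The common window is the intersection of per-subject intervals;
   subjects whose interval cannot overlap it are flagged for exclusion,
   never dropped silently. The largest admissible level is located by
   bisection, treating small-worldness as monotone in density (it degrades
   as the graph fills in); windows wider than the 16-level cap keep the
   levels adjacent to the criterion-determined maximum. Explicit
   `k_min`/`k_max` overrides skip the search when a study prescribes its
   window.

6. **Metrics.** Per network: Shannon entropy of the degree distribution
   (natural log, so regular graphs score 0), population variance and Pearson
   kurtosis (`m4/m2^2`, no −3; before/after differences are unaffected by
   the convention, which is recorded in the manifest; kurtosis is reported
   missing for regular graphs), mean geodesic distance `D` (BFS hop counts;
   `+inf` for disconnected graphs rather than an error — the feasibility
   criteria exclude such graphs from analysis windows), clustering
   coefficient `C`, global efficiency `E_g` (`1/inf = 0`), and local
   efficiency `E_l`. Nodes with fewer than two neighbors contribute 0 to
   `C` and `E_l` rather than being excluded from the denominator, and
   local-efficiency distances are measured inside each neighbor-induced
   subgraph; both follow the standard brain-connectivity-toolbox convention
   (the defining sums are ambiguous on these points).

7. **Null ensembles.** Degree-preserving randomization by repeated edge
   swaps: two edges `(i,j)`, `(m,n)` with four distinct endpoints are
   rewired to `(i,m)`, `(j,n)` only when both replacements are absent. The
   degree multiset — hence the degree distribution and its entropy — is
   conserved exactly, so ensembles are iso-entropic; non-conserved metrics
   are summarized by the ensemble mean and reported as ratios
   (`D/D_rand`, `C/C_rand`, ...). The swap budget is 10x the edge count of
   successful swaps per member (a standard mixing heuristic; the mixing
   length is not critical because only conserved quantities are asserted
   exactly), with a proposal cap of 100x the edge count that returns the
   best-effort graph with a warning on rigid inputs (paths, complete
   graphs). Each of the 30 members draws from an independent random
   substream derived from `(seed, member index)`, so members are
   order-independent and reproducible.

8. **Group statistics.** Per metric and level, a paired-sample Student's
   t-test on the (after − before) differences (two-sided, `df = n - 1`;
   identical to a one-sample t on the differences), with table flags
   following the reporting convention `bold` for `0.005 <= p < 0.05` and
   `*` for `p < 0.005`. No multiple-testing correction is applied across
   the grid levels: levels are strongly dependent (nested networks), and
   per-level p-values with flags are the quantity of interest. All-zero
   differences give `t = 0, p = 1`; nonzero constant differences have
   undefined t and are reported missing with a note. Per-subject
   five-number summaries use median-unbiased order-statistic interpolation
   for the quartiles. Behavioral/motion covariates (e.g. dissociative-scale
   or frame-displacement deltas) are related to per-subject metric changes
   by Pearson correlation with exact two-sided p-values (`df = n - 2`); no
   fixed critical-r shortcut is hard-coded.

## Synthetic paired datasets

The generator emulates the *shape* of a paired pharmaco-fMRI study — by
default 7 subjects x 2 conditions, 104 regions x 150 volumes at TR = 1.7 s,
6 modules — with a known planted effect. Region `i` in module `m` follows

    x_i(t) = u_i * (a f_m(t) + b g(t)) + sigma eps_i(t)

where `f_m` and `g` are unit-variance sums of eight random-phase sinusoids
inside the scale-3 passband (band-limiting is built into the generative
spectrum rather than applied by post-hoc filtering, so it is explicit and
testable), `eps` is white noise, and `a`, `b` are set from the design
targets `rho_in = 0.45`, `rho_out = 0.15` (within/between-module raw
correlations for unit gains; realistic for band-passed ROI data). The
paired contrast is gain heterogeneity: "before" gains are tightly spread
(`u = max(0.15, 1 + 0.05 z)`), "after" gains widely spread
(`u = max(0.15, 1 + 1.0 z)`), creating hubs and weakly-coupled regions.
Because the pipeline matches edge density across conditions, this changes
the *shape* of the degree distribution — broader, higher-entropy — without
a mean-connectivity confound, which is exactly the effect the analysis is
meant to detect. Setting both dispersions equal gives an exchangeable null
configuration for type-I studies. Everything derives from a single seed
through named substreams; identical specs give byte-identical data.

The designed comparison window for default-size datasets is
`DESIGNED_LEVEL_RANGE = (14, 29)`: 16 levels in steps of 1, all above the
sparsity floor. The window sits at lower density than typical empirical
studies report because, with 150 volumes of band-limited synthetic signal,
the count-based degree entropy of *both* conditions saturates toward its
`ln 104` ceiling at high density and the planted contrast washes out;
real recordings have a lower baseline spread. Within the designed window
the planted increase is detected (paired-t `p < 0.005` at a majority of
levels, higher mean entropy after at every level) in essentially every
seed, and under the null configuration the central-level rejection rate is
consistent with the nominal 5%.

What the generator does *not* emulate: hemodynamics, spatial structure and
smoothing-induced spatial autocorrelation, scanner drift and physiological
noise spectra, motion artifacts, and the temporal autocorrelation profile
of real BOLD noise (its noise is white outside the signal band). Passing
tests therefore demonstrate that the pipeline recovers degree-distribution
broadening from modular, band-limited correlated signals at realistic
sample sizes — not that it is robust to every artifact of real fMRI.

Graph-level generators complement the time-series path: degree sequences
with narrow (regular, zero-entropy) or wide profiles, parity- and
graphicality-repaired (Erdős–Gallai checked), realized as simple graphs by
stub matching with bounded swap repairs.

## Numerical choices and degenerate inputs

- Shortest paths: breadth-first search via `scipy.sparse.csgraph`;
  distances are exact hop counts, so oracle comparisons use a 1e-12
  absolute tolerance (pure float-summation slack).
- A zero-variance region cannot carry a correlation; its row and column are
  gated out with a warning rather than poisoning the matrix.
- Degenerate t-tests and correlations (zero variance) are reported missing
  with an explanatory note, except the genuinely informative all-zero
  difference case (`t = 0, p = 1`).
- Rank-deficient nuisance designs fail fast, naming the dependent columns.
- The edge-rank tie-break and all random substreams make every stage
  deterministic given the config seed; the run manifest records every
  convention and suffices to re-run the analysis identically.

## Problem sizes used in the shipped checks

Oracle equivalence uses 200 random graphs with at most 12 nodes (where
brute-force enumeration is exact); null-model conservation uses 30-member
ensembles on 20 random sources; the grid-construction contract runs the
full feasibility search (30-member ensembles) on a two-subject dataset at
the default 104 x 150 size; effect recovery uses 50 generator seeds and
type-I control 200 replicate seeds, both at full default size with the
entropy-only fast path. These sizes were chosen so the whole battery runs
comfortably on a single CPU while keeping every check at the full default
data shape where it matters.

## Known limitations

- The significance gate uses nominal degrees of freedom on autocorrelated
  wavelet coefficients (anti-conservative); it screens edges, it does not
  provide calibrated edge-level inference.
- Small-worldness is treated as monotone in density during the bisection
  for the window maximum; borderline non-monotonicity near the boundary can
  shift the window by a level or two between seeds.
- Entropy of a 104-node degree histogram is a count-based estimate with a
  hard `ln 104` ceiling; comparisons at very high density compress toward
  that ceiling (see the designed-window discussion above).
- Weighted and directed networks, betweenness, assortativity, modularity
  detection, non-parametric group tests, and FDR control are out of scope.
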