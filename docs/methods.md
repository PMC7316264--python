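# Methods

This note documents the models, defaults and numerical choices behind
`rsconn`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort model

Each (group, timepoint) cell has a target correlation matrix built from
a modular baseline: ROIs in the same community correlate at
`base_within_r = 0.35`, across communities at `base_between_r = 0.05`.
Planted effects are expressed on the Fisher-z scale —
`r' = tanh(atanh(r) + delta_z)` — and applied only to the
(experimental, second-timepoint) cell, so downstream z-scale statistics
see an additive interaction shift of exactly `delta_z` (default −0.4).
The default planted edge set is a bilateral fronto-temporal subnetwork
of 11 edges over 13 nodes, every edge touching one of four inferior
frontal parcels; all planted edges are guaranteed present in the
structural backbone template.

If a shifted target is no longer positive definite it is repaired by
eigenvalue clipping at 1e-6 followed by diagonal renormalization. The
generator *asserts* that this projection moves non-planted cells by less
than 0.01 and raises an error otherwise, rather than silently distorting
the baseline: very strong shifts (e.g. `delta_z ≈ −2.5` concentrated on
one hub) are therefore rejected instead of approximated.

Per subject and timepoint, `n_volumes = 242` samples are drawn i.i.d.
from a zero-mean multivariate normal with the cell's target correlation
(Cholesky factorization), then contaminated by

- two shared nuisance source signals (unit-variance white noise,
  standing in for mean white-matter and CSF signal), each added to every
  ROI at `nuisance_amplitude = 0.3` and recorded verbatim as nuisance
  channels, mirroring a real pipeline's WM/CSF averages;
- per-ROI polynomial drift: Legendre polynomials of degree 1..2
  (`drift_order = 2`) with coefficients drawn at s.d. 0.5 of the signal
  scale, emulating slow scanner (thermal) drift.

Cohort sizes default to 14 + 12 subjects at TR = 2 s, matching the
longitudinal two-group design the pipeline targets. Structural
connectomes are per-subject noisy copies of a common binary template
(dense within communities, 30% between), with each off-diagonal cell
flipped independently at `structural_flip_rate = 0.05` (symmetry
preserved, planted edges never removed).

**What the generator does not emulate:** hemodynamic convolution and
1/f temporal structure (samples are white before contamination), head
motion and its artifacts, spatially correlated noise, imperfect nuisance
measurement (the recorded channels equal the injected signals, so
regression removes them exactly), and distance-dependent structural
noise. Passing recovery tests therefore show the *statistical* chain is
correct under the assumed covariance model, not that the pipeline is
robust to real-scanner artifacts.

All randomness flows from `(spec.seed, subject_seed)` seed tuples into
`numpy.random.default_rng`, making every bundle reproducible
byte-for-byte after serialization.

## Preprocessing

Stage order: discard initial volumes (default 5 of 242) → nuisance
regression → polynomial detrend (default order 2) → band-pass →
Fisher z. The order is fixed but each stage can be disabled; nuisance
regression and detrending are idempotent projections, so repeating them
is harmless. The band-pass is a zero-phase (forward–backward) 4th-order
Butterworth with cutoffs 0.01–0.1 Hz; the contract is stated as
frequency-response bounds (≥ 90% amplitude retained mid-band at
0.05 Hz, ≤ 10% at 0.002 and 0.2 Hz for TR = 2 s) rather than a filter
family, and the tests measure exactly that. Correlations are clipped to
|r| ≤ 1 − 1e−7 before `atanh` so z stays finite; the diagonal is fixed
at 0 by convention.

## Backbone and mixed matrices

The consensus vote is inclusive (≥ threshold), so with 26 subjects and
threshold 0.5 an edge present in exactly 13 subjects is kept and one in
12 is dropped. Weighted structural inputs (fiber counts) are binarized
at > 0 before voting; no minimum-count criterion is applied beyond
whatever upstream tractography filtering produced the inputs. Both
groups are pooled into a single template so group differences in
structure cannot bias the functional comparison.

## Efficiency measures

Both efficiencies are computed on the member-induced subgraph of the
mixed matrix (the alternative — whole-graph paths restricted to member
endpoints — is deliberately not implemented). Weights map to lengths by
the reciprocal; negative Fisher-z weights carry no path and are treated
as absent edges for efficiencies, while connectivity strength keeps
their sign (strength is defined on correlations, efficiency on flow).
Local efficiency uses the weighted cube-root variant: neighbor-pair
shortest paths are computed on the neighborhood subgraph with
cube-rooted lengths, each ordered pair (j, h) of neighbors of i
contributing `w_ij^(1/3) w_ih^(1/3) / d_jh`, normalized by
`k_i (k_i − 1)`; nodes with fewer than two neighbors score 0, and the
network value is the unweighted mean over member nodes. Shortest paths
use Dijkstra (scipy); unreachable pairs contribute 0 through `1/∞ = 0`.
Both kernels are verified against brute-force path enumeration.

## ANOVA engine

With a two-level within factor the split-plot decomposition is exact on
subject summaries: the Group effect is the pooled two-sample t (squared)
on per-subject means; the interaction is the pooled two-sample t
(squared) on change scores; the Timepoint effect tests the *unweighted*
mean of the two group change means (the type-III convention, chosen
because unbalanced 14/12 designs are the norm here and this matches
standard commercial-software output). All effects have df (1, N−2).
Degenerate inputs (zero variance and zero effect) return F = 0, p = 1
rather than NaN. The engine is vectorized over edges, so the 8256-edge
scan is a single pass.

The FDR step is Benjamini–Hochberg step-up (via statsmodels) on the
interaction p-values across the tested family — by default all
upper-triangle edges; restricting the family to backbone edges is a
config option since either family is defensible. Post-hoc tests are
uncorrected two-tailed t-tests at α = 0.05, computed only for flagged
edges.

## Problem sizes and statistical behavior

The default recovery experiment (Δz = −0.4 at 11 edges, 14/12 subjects,
237 retained volumes) is deliberately run at the full 129-ROI scale;
one simulated cohort takes well under a second through the whole chain.
A useful design fact: band-pass filtering to 0.01–0.1 Hz leaves roughly
`2·B·T ≈ 85` effective samples per series (B = 0.09 Hz, T = 474 s), so
the sampling s.d. of a z-edge is ≈ 0.11 rather than the
`1/√(T−3) ≈ 0.065` an i.i.d. count would suggest. At the BH threshold
implied by 11 true effects in an 8256-edge family (|t| ≈ 4.9 at df 24),
per-edge detection power is therefore ≈ 0.85–0.95 and the scan
typically recovers 9–11 of the 11 planted edges per cohort, with
occasional misses clustering because the step-up threshold adapts to the
number of rejections. Under the global null the scan flags essentially
nothing (0 edges in 20/20 simulated null cohorts).

Graph-kernel correctness is checked exhaustively against enumeration on
all ≤ 4-node graphs over weights {0, 0.25, 0.5, 1} and on every 5-node
edge topology with rotating weight assignments from {0.25, 0.5, 1} —
about 7000 graphs, chosen to cover every path/neighborhood code path
while keeping the suite fast — plus 100 random 6-node graphs per kernel.

## Known limitations

- The generator's white temporal spectrum makes band-pass filtering
  purely variance-inflating; with hemodynamically realistic (already
  band-limited) signal the same pipeline would lose less information.
- Negative-weight handling in weighted efficiency and the choice of FDR
  family are field-ambiguous; both are explicit config choices here.
- No motion scrubbing, global-signal regression, spatial smoothing, or
  permutation-based (cluster/NBS-style) component inference.
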