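# Methods

## Model and procedure

`jrpnet` treats each protein residue as a dynamical system observed
through one scalar time series Z₁…Z_N (in practice a per-residue Cα RMSD
trace sampled at even spacing from an MD trajectory).  The analysis has
four stages.

**Phase-space reconstruction.**  Each series is delay-embedded,
X_i = (Z_i, Z_{i+d}, …, Z_{i+(m−1)d}), giving N_s = N − (m−1)d states.
The delay d is the first strict local minimum of the time-lagged mutual
information; the dimension m is the smallest for which the
false-nearest-neighbor fraction drops below 1%.  Each residue gets its
own (d, m); a `global_embedding` option forces the per-run maximum on all
residues when aligned state counts are preferred.

**Recurrence.**  A residue recurs at time pair (i, j) when
‖X_i − X_j‖ ≤ ε (Euclidean norm; the boundary case recurs, matching a
Heaviside step that is 1 at zero).  ε is calibrated per residue by exact
quantile selection on the sorted list of all pairwise state distances so
that the recurrence rate — ones over all N_s² matrix cells, diagonal
included — is the smallest achievable value at or above the 3% target.
The achieved rate is recorded per residue in the run manifest.

**Joint recurrences and networks.**  The joint recurrence plot of two
residues is the elementwise AND of their recurrence matrices.  The edge
weight of a pair is its accumulated strictly-upper-triangle joint count
divided by the pair's Cα–Cα distance in the reference structure; no
cutoff distance is applied.  The diagonal is excluded from counting
because every residue trivially recurs to itself at i = j, which would
add the same constant to every pair.  When per-residue embeddings give
different N_s, all matrices are truncated to the common leading window
(first N_s,min states), preserving simultaneity of time indices; the
truncation is recorded in the manifest.  Two comparison networks are
built over the same nodes: an unweighted network joining residues within
7 Å, and a contact-weighted network whose weights are inter-residue
atomic contact counts (supplied as a table, or approximated as heavy-atom
pairs within 4.5 Å — a plain geometric count, not a
surface-complementarity contact classification).

**Centrality and significance.**  Betweenness B is the raw count of
shortest paths through a node over unordered source–target pairs with
fractional credit for ties; closeness is C_n = (j−1)/Σ sd(i, n).  On a
weighted graph a weight→length conversion is needed and nothing in the
residue-network literature fixes it; `jrpnet` uses path_length = 1/weight
(stronger interaction ⇒ shorter path), isolated in `edge_path_length` so
−log-based costs can be swapped in.  On disconnected graphs closeness
uses only the r reachable nodes with (r−1)/Σ scaling and betweenness
counts paths within components.  B and C are standardized to z-scores
with the population SD; residues with z_B > 2 or z_C > 1.5 are reported
together with their first-degree neighbors that are themselves
significant or carry a user annotation.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| target_recurrence_rate | 0.03 | per-residue recurrence-matrix density the threshold calibration aims at |
| cutoff_distance | 7.0 Å | edge criterion of the unweighted comparison network |
| z_B / z_C thresholds | 2.0 / 1.5 | significance cutoffs on the standardized centralities |
| n_bins | ⌊√N⌋, capped at 32 | histogram bins of the MI estimator |
| max_lag | min(100, N/2 − 2) | MI scan range for delay selection |
| max_dim, fnn_threshold | 10, 0.01 | FNN search range and acceptance fraction |
| R_tol, A_tol | 15, 2σ | Kennel double criterion for a false neighbor |
| atom contact cutoff | 4.5 Å | heavy-atom distance defining a contact in the stand-in counter |

## Numerical choices

* **MI estimator**: equal-width bins over each marginal's observed range,
  with the Miller–Madow correction subtracted and the result clamped at
  zero.  The plug-in histogram MI is biased upward by roughly
  (B−1)²/2N nats — about 0.1 nat at 32 bins and N = 1000 — which would
  make independent noise read as substantially dependent.  The correction
  leaves the first-minimum location of structured signals intact.
* **Delay fallback**: when no strict local MI minimum exists in the scan
  range (common for noise-dominated series), delay 1 is used and flagged.
  Likewise, when the FNN fraction never drops below threshold, max_dim is
  used and flagged.  Flags propagate to the run manifest.
* **Threshold boundary**: a distance exactly equal to ε recurs
  (Θ(0) = 1), so ties at the calibrated quantile all recur and the
  achieved rate can exceed the target by the tie mass; it is recomputed
  after selection and reported.
* **Degenerate inputs**: a constant series has MI 0 at every lag, FNN
  fraction 0 (no distinguishable neighbors) and recurrence rate 1 at any
  positive ε; calibration flags this and returns a tiny positive ε.
  Standardizing an all-equal centrality vector raises a
  `DegenerateDistributionError` rather than dividing by zero.
* **Counting**: joint counting is done on bit-packed upper triangles
  (AND + popcount), which keeps the all-pairs accumulation for 165
  residues × ~1000 states (~13.5k pairs of ~10⁶-cell matrices) in the
  tens of seconds on one CPU.
* **Triangle convention**: counting one triangle rather than the full
  symmetric matrix halves every pair's count uniformly, so centrality
  rankings and z-scores are unaffected; only absolute counts depend on
  the convention.

## The synthetic generator

Real inputs require an MD trajectory; the generator replaces them with a
system whose ground truth is known.  Each residue is a stationary AR(1)
process (autocorrelation 0.9 by default, giving series with nontrivial
embedding structure, unlike white noise).  A coupled pair shares a latent
AR(1) driver mixed with variance-preserving weights,
z_i = √(1−c)·base_i + √(c/k_i)·Σ_p driver_p, where c is the coupling
strength and k_i the number of pairs containing residue i; the shared
driver makes both members revisit earlier states at the same instants,
which is precisely the signal joint recurrences accumulate, while the
variance normalization keeps ε-calibration comparable across residues.
Reference coordinates lie on a straight chain with 3.8 Å spacing, the
Cα–Cα distance of a real polypeptide, so geometric expectations
(path-graph topology under a 7 Å cutoff, exact pair distances) are
analytic.

What the generator does **not** emulate: secondary/tertiary structure,
anharmonic or multi-timescale dynamics, solvent physics, and realistic
contact geometry.  Passing tests therefore demonstrate that the pipeline
recovers planted couplings from stochastic series under controlled
conditions — not that it recovers hotspots of any particular protein.

Two statistical facts about the synthetic conditions are worth stating
explicitly.  First, with autocorrelated series the recurrences of every
residue concentrate near the matrix diagonal, so the joint density of
independent pairs sits well above the naive rate² product; the product
null is exact only for white-noise series with trivial (m = 1)
embedding, and that is the condition under which the null behavior is
tested.  Second, because edge weights divide by distance, on a straight
chain the weights of distant coupled pairs must be compared against
uncoupled pairs at the same chain separation; comparing against all
pairs conflates coupling with geometry.

## Problem sizes used in the test suite

Unit and property tests run on series of 100–5000 frames and graphs of
up to 15 nodes, where brute-force oracles (double-loop recurrence
counting, Floyd–Warshall distances, path-count betweenness) are exact.
The end-to-end feasibility check runs the full pipeline at 165 residues ×
1000 frames — the scale of a single-domain protein over a 10 ns
trajectory sampled every 10 ps — and completes in well under a minute.

## Known limitations

* The weight→length conversion (1/weight) is a convention, not a derived
  quantity; rankings can change under −log costs on graphs with heavy
  weight ties.
* Per-residue (d, m) selection makes state counts differ across residues;
  the leading-window truncation discards up to (m_max−1)·d_max trailing
  states of the shorter embeddings.
* The contact stand-in counts heavy-atom pairs within 4.5 Å and does not
  reproduce surface-complementarity contact analysis.
* ASA values are accepted as input; computing solvent accessibility from
  coordinates is out of scope.
* No RQA line-based measures (determinism, laminarity) and no
  cross-recurrence analysis; the package is deliberately limited to
  recurrence rates and joint-recurrence counting.
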