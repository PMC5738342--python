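# Methods

`phasetrack` quantifies the morphodynamics of confluent endothelial
monolayers from phase-contrast time-lapse movies: it segments cells, links
them into trajectories, and computes the junction and migration statistics
used to study VE-cadherin remodelling (Rel-VEcad-C, JAIL plaque metrics,
elongation, accumulated/Euclidean distance).  This note documents the
models, the parameters that matter, the synthetic benchmark, and the
numerical choices.

## Segmentation: a binary MRF with robust higher-order potentials

Each frame is segmented independently.  The label field x ∈ {0,1}^(H×W)
has energy

    E(x) = w_u Σ_i u_i(x_i)
         + β Σ_(i~j) [x_i ≠ x_j]                       (4-neighbour Potts)
         + Σ_c min(γ, γ · min(k_c, n_c − k_c) / (q n_c))   (robust P^n-Potts)

where k_c is the number of foreground pixels in clique c of size n_c.  The
higher-order term encourages the pixels of each clique — a region of a
seeded watershed oversegmentation — to agree, but its truncated-linear form
saturates once a fraction q of the clique dissents, so oversegmentation
errors cost a bounded amount.  `truncation_q` defaults to 0.3.

**Unary term.**  Phase-contrast optics render the cell body dark and wrap
it in a bright halo.  The halo is what separates adjacent bodies in a
confluent sheet, so it must *not* count as foreground: if it did, touching
cells would fuse into one blob with no constriction for any splitter to
find.  The per-pixel foreground feature is therefore the rectified smoothed
darkness, max(0, median(I) − I)/sd(I), Gaussian-smoothed at radius/2
(radius default 4 px).  Normalising by the frame's intensity spread makes
the feature invariant under affine intensity rescaling.  An Otsu split of
the per-frame feature distribution provides a two-class log-likelihood
ratio f_i = (feature_i − t)/s; the unary energies are u_i(1) = −f_i/2,
u_i(0) = +f_i/2.

**Probabilities.**  `segment_frame` returns Gibbs marginals of the field at
temperature T (default 1), estimated by a seeded Rao-Blackwellised Gibbs
sampler: raster-order single-site updates, accumulating the exact
single-site conditional σ(ΔE/T) at every visit rather than the binary
sample.  This estimator is exact (to machine precision) in the factorised
limit β = γ = 0, and its Monte-Carlo error is far below the binary-sample
estimator elsewhere.  We chose sampling over a deterministic mean-field or
belief-propagation scheme after measuring both on 4×4 fields against
exhaustive 2^16 enumeration: mean field erred by up to 0.32 in per-pixel
marginal probability near critical pairwise coupling and loopy BP by up to
0.065, while the Gibbs estimator stays below ~0.02 at its default budget
(500 burn-in + 4000 averaged sweeps).  The sampler seed is part of
`MrfParams`, so identical inputs give bit-identical output.  The sweep
kernel is numba-compiled; movie-scale runs use a reduced budget (50 + 150
sweeps per frame, `pipeline.MOVIE_MRF_PARAMS`), which is ample for blob
detection: the per-pixel standard error there is ≈ 0.04, far below the 0.5
detection threshold's margin.

Defaults: w_u = 1, β = 0.5, γ = 0.5, one clique per ~16×16 px block,
T = 1, binarisation threshold τ = 0.5 (inclusive).

## Blob hypotheses: maximal inscribed ellipses

Cell candidates are ellipses that *consist of* sufficiently-foreground
pixels and cannot be enlarged without ceasing to do so.  Concretely, an
ellipse is *admissible* when (i) its major axis is within bounds, (ii) at
least 95% of its interior pixels have probability ≥ τ (interior pixels
outside the image count as failing), and (iii) its mean interior
probability — the hypothesis *support* — is ≥ τ.  Generation:

1. threshold the probability map at τ and label 8-connected components;
2. seed at local maxima of the smoothed distance transform (one peak per
   blob core; merged blobs get one per core), minimum separation
   2·min_axis;
3. split multi-seed components by marker-controlled watershed on the
   inverted distance transform (cuts at constrictions);
4. fit a second-moment, area-matched ellipse to each basin (with the 1/12
   unit-pixel correction), then grow it isotropically in 5% steps from the
   smallest admissible size and keep the last admissible scale.

Because growth stops exactly when one more 5% step would violate
admissibility, every emitted hypothesis is maximal by construction and the
property can be re-verified post hoc by independent pixel counting.  The
95% coverage fraction tolerates discretisation fringe at the boundary
without letting candidates leak through it; demanding 100% would make the
criterion brittle to single boundary pixels, while using the mean support
alone would let a candidate overshoot the true boundary by up to √2 in
linear scale before its mean dropped to τ.  Near-duplicates from plateau
seeds (IoU > 0.95) are removed at generation; a milder non-maximum
suppression (`deduplicate`, IoU > 0.6) runs before tracking.  Overcounting
is deliberate — candidates form a superset and the trajectory model makes
the final call.

## Tracking: a joint model over interacting trajectories

A trajectory is a contiguous sequence of hypotheses, one per frame; it may
start and end at any time, and a missing detection terminates it (no gap
bridging).  Its log score is

    log_birth + log_death
    + Σ_elements (log support + log_coverage)
    + Σ_transitions [ N₂(Δcentre − v̂; σ_pos²)
                    + N(Δlog a; σ_shape²) + N(Δlog b; σ_shape²)
                    + WN(Δθ; σ_theta²) ]

with v̂ the previous displacement (constant-velocity prediction); the first
transition uses v̂ = 0 with σ_pos doubled, since a velocity needs two
points.  WN is a wrapped normal on the half-circle (orientations are
π-periodic).  A collection of trajectories adds the interaction term
−κ · (same-frame pairwise interior overlap in px²), encoding monolayer
non-overlap; κ = ∞ forbids overlap outright.

Defaults and why:

| parameter    | default | rationale |
|---|---|---|
| σ_pos        | 2 px/frame | detection-centroid jitter (~1–2 px) dominates true acceleration noise |
| σ_shape      | 0.05      | 5% scale-step quantisation of the axis estimates |
| σ_theta      | 0.15 rad  | moment-fit orientation jitter for mildly elongated cells |
| log_birth    | −4        | a fragmentation (extra birth+death) must cost clearly more than one transition (~+2 to +4) can gain; −4 keeps single-frame births rare but reachable by the sampler |
| log_death    | −1        | mild end penalty |
| log_coverage | +2        | rewards explaining detections; with the transition constants it makes tracks of ≥3 frames profitable |
| κ_overlap    | 0.01 /px² | neighbouring candidates legitimately share halo rim (~100 px² of ~2500 px² cells → penalty ≈ 1), duplicates share >25% (penalty ≥ 6 per frame, decisive) |

**Inference.**  Metropolis–Hastings over collections with five reversible
structural moves (mixture weights in parentheses): birth of a singleton
from an unassigned hypothesis (.20), death of a singleton (.20), extend a
trajectory by one frame at either end (.25), truncate one element from
either end (.15), and switch — swap the tails of two trajectories after a
common frame (.20).  Death is restricted to singletons so that every move
has an exact single-move inverse with a computable proposal ratio; tracks
are dismantled by truncation.  The tail-swap proposal is symmetric because
the set of trajectory pairs alive at the chosen frame pair is invariant
under the swap.  Extension candidates are gated at 25 px centre
displacement (a proposal restriction only, not part of the model).  Scores
are maintained incrementally: each move re-scores at most two trajectories
and touches only the overlap partners of the hypotheses it moves.  Chains
on movies start from a deterministic greedy linking; small-instance
analyses can start from the empty collection.

**Decision.**  The final tracking minimises posterior expected loss under a
symmetric per-link/per-inclusion 0–1 loss: every link and inclusion whose
marginal frequency over the post-burn-in samples (default burn-in 0.3)
exceeds ½ is retained, and retained links are assembled greedily by
descending frequency into contiguous trajectories.  Under this loss the
threshold-½ rule is the exact Bayes rule; conflicts are impossible in
exact arithmetic (marginals of competing links for one hypothesis sum to
≤ 1) and are resolved by frequency order if ties arise.  The *average
number of tracked cells* over a frame range is the mean number of alive
trajectories per frame.

## Morphometrics

* **Elongation factor** — a/b of the second-moment best-fit ellipse
  (closed-form Green's-theorem polygon moments for outlines; exact a/b for
  ellipses).
* **Perimeter** — polygon edge-length sum × pixel size (µm).
* **Migration** — accumulated distance (Σ step lengths), Euclidean distance
  (start→end), mean velocity (accumulated / elapsed, µm/h), directionality
  (Euclidean/accumulated, NaN for a stationary cell).
* **Rel-VEcad-C** — integrated junction-channel intensity over a ribbon ROI
  divided by the ROI's junction length (a.u./µm).  The integration is raw
  by default, matching the definition of the quantity; optional
  annulus-median background subtraction is available for offset-carrying
  images but is *not* the default because on tessellated monolayers the
  2-px annulus of one cell's ribbon contains its neighbour's ribbon, which
  biases the median.  A polyline ROI is rasterised at width 3 px.
* **Total VE-cadherin estimate** — mean perimeter × mean Rel-VEcad-C; by
  construction invariant when shape change conserves the per-cell junction
  pool.
* **JAIL plaques** — count and areas (µm²) of 8-connected components of a
  supplied plaque mask above a minimum area.  Sizes are reported as areas;
  plaque extent along the junction would be an alternative convention, and
  the choice is recorded here because published figures do not state one.
  Automatic plaque detection from raw movies is out of scope; masks come
  from a thresholded plaque-marker channel.
* **Pole/lateral partition** — boundary points of an elongated cell
  (elongation factor > 1.5) are labelled *pole* when their direction from
  the centroid lies within ±45° of the major axis (either end), else
  *lateral*.  Both the half-angle and the cutoff are declared, tunable
  conventions.

Coordinates are 0-based with pixel centres at integer positions; angles are
radians in [0, π); CSV floats carry 6 significant digits.

## Synthetic monolayer

The simulator provides ground truth for recovery tests.  Cells are
non-overlapping ellipses with constant-velocity kinematics plus Gaussian
acceleration noise (σ_acc = 0.3 px/frame²), smooth log-axis and orientation
drift, reflecting boundaries (no cells enter or leave, keeping the true
tracked-cell count constant), and a soft pairwise repulsion that pushes
overlapping pairs apart along their centre line each frame until every
pairwise interior overlap is below 2% of the smaller area.  An elongating
subpopulation (default 20%) grows its major axis by 1%/frame with
antisymmetric log-axis increments so that the area π·a·b is conserved
exactly — the shape programme that dilutes a fixed junction pool over a
growing perimeter.  Defaults: 30 cells in 512×512 px, 60 frames at 300 s,
0.65 µm/px, axes a ∈ [28, 36] px, b ∈ [20, 28] px (≈ one-third field
coverage), initial speeds 0.3–1.0 px/frame (≈ 4–12 µm/h).

Two renderers emulate the measurement channels.  *Phase contrast*: uniform
background (100), cell bodies 30 units darker, a 2-px halo band 40 units
brighter, additive Gaussian noise (σ = 5, 8-bit-like scale).  *Junction
fluorescence*: cell territories are the influence tessellation of the
ellipses (nearest normalised elliptical distance); each cell deposits a
fixed total intensity (default 1000 a.u., equal across cells) spread
uniformly over its boundary ribbon, so the integrated ribbon intensity
equals the emitted total exactly and line density is inversely proportional
to boundary length.

What the renders do *not* emulate: real phase-contrast optics (no transfer
function, shade-off, or uneven illumination), intensity heterogeneity
between cells, mitosis, apoptosis, or cells crossing the field boundary.
Passing the recovery tests therefore shows the pipeline is correct and
self-consistent under the stated imaging model, not that it is robust to
every artefact of real microscopy.

## Validation and problem sizes

The test suite checks, among others: segmentation marginals within 0.05 of
exhaustive-enumeration Gibbs marginals on 20 random 4×4 frames (all
weights ≤ 1, 2 cliques); the factorised limit to 1e-10; the 1.05-scaling
maximality oracle for every hypothesis on 50 random probability maps;
agreement of the sampled Bayes decision with the exhaustively enumerated
MAP on 20 sharply peaked tiny instances (3 frames × ≤3 hypotheses, top-two
score gap > 2 log-units, 20 000 iterations); end-to-end recovery on the
default simulated movie (identity-consistent match rate ≥ 0.90 at IoU 0.5,
centre RMSE ≤ 2 px, average tracked cells within ±1 of 30, at 30 000
sampler iterations); exact junction-pool conservation on noise-free
renders; and bit-reproducibility of every stage under fixed seeds.  These
sizes keep the whole suite within a few minutes on one CPU while leaving
each check statistically meaningful; `scripts/acceptance.py` recomputes the
same quantities from scratch for any seed.

## Known limitations

* No gap bridging: a single missed detection splits a track (the identity
  is usually preserved by the majority-label convention in evaluation, but
  fragment counts rise).
* No division or merge events; mitosis in real movies will appear as a
  track end plus two births.
* The MRF weights are fixed, not learned; heavily textured debris can
  segment as foreground.
* Exact ellipse-intersection areas are replaced by 1-px-grid counts
  everywhere (overlap penalties, IoU); the quantisation error is well below
  the penalty and matching scales for cell-sized ellipses, but would not be
  for structures a few pixels across.
* The Bayes decision thresholds marginals independently; it can in
  principle assemble a collection whose joint score is slightly below the
  sampled MAP when the posterior is flat (not observed under the default
  study conditions).
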