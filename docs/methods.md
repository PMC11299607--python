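# Methods

## The indexing problem

A serial-crystallography frame records Bragg peaks from a single randomly
oriented micro-crystal (occasionally a few crystals).  Each detector peak
maps to a scattering vector on the Ewald sphere of radius 1/λ centred at
−ẑ/λ:

    s = (1/λ) (p/|p| − ẑ),   p = (x − x₀, y − y₀, D)

with `D` the sample–detector distance and `(x₀, y₀)` the beam centre.  If
the frame contains a crystal with reciprocal basis `A` (columns a\*, b\*,
c\*), the non-spurious spots satisfy the Laue condition

    s_q = A · (h_q, k_q, l_q)ᵀ,  (h, k, l) ∈ ℤ³,

up to measurement error.  The unit cell — and hence the *shape* of `A`, an
ideal basis `B₀` known up to orientation — is assumed known.  Indexing
means recovering the rotated basis `Ã ≈ R·B₀`, the integer indices, and the
subset of spots (at least `k_min` of them) whose residuals
`|Ã·hkl_q − s_q|` all fall below a bound β.  The remaining spots are
treated as outliers (false peaks, noise, other crystals).

## Pipeline

1. **Vector sampling.**  Candidate *real-space* lattice vectors are taken
   from Fibonacci (golden-angle) lattices on spheres whose radii are the
   real cell lengths a, b, c — `lattice_size` points per axis,
   deterministic.  Real-space vectors admit a per-vector Laue test: for a
   true lattice vector v, every lattice spot gives an integer `s_q · v`.
   Cells with equal lengths share one sphere.
2. **Vector ranking.**  Each candidate scores
   `Σ_q w(s_q · v)` with the smooth kernel `w(t) = (1 + cos 2πt)/2`,
   maximal at integers, zero at half-integers (a hard-count kernel is
   available via `score_kernel="threshold"`).  The top `num_top_vectors`
   per axis survive.
3. **Basis attachment and spinning.**  A rigid copy of `B₀` is rotated so
   the matching real axis aligns with each surviving vector, then spun
   about it; one snapshot every `360/angle_resolution` degrees.  Every
   snapshot preserves the ideal metric exactly — candidates are rotations
   of `B₀`, never sheared.
4. **Basis ranking.**  Whole bases score by the mean three-component
   closeness of `Ã⁻¹ s_q` to integers, summed over spots; the top
   `num_top_solutions` enter robust fitting.
5. **Robust fit** (per candidate; see below).
6. **Shape penalty and selection.**  A fitted basis is converted back to
   cell parameters; `penalty = Σ|Δlen|/len + Σ|Δang|/90°`, and a solution
   is valid only when every length is within `length_tol` (relative) and
   every angle within `angle_tol` (degrees) of the ideal cell.  Valid
   solutions rank by (inlier count desc, penalty asc) and are emitted
   greedily while each new solution shares < 50 % of its inliers with the
   ones already emitted, up to `max_lattices` — this is how two-crystal
   frames yield two solutions without extra iterations.

The pipeline contains no randomness: identical inputs and parameters give
identical output.  Batching (`prune_and_pad` to a fixed `max_spots` per
frame, lowest-resolution spots kept, zero rows masked out) is purely an
execution layout; `index_batch` is defined to agree exactly with per-frame
indexing, and masked padding rows can never score, fit, or become inliers.

## Robust fitting: dual least trimmed squares with threshold annealing

Given a candidate basis, each spot gets *induced* Miller indices
`hkl_q = round(Ã⁻¹ s_q)` (componentwise, ties to even — the only
discretisation in the method).  For a fixed assignment the best basis is an
ordinary least-squares problem with closed-form solution
`Ã = S Mᵀ (M Mᵀ)⁻¹`; with exact indices and no noise a single update lands
on the true basis.  Outliers are removed by a dual form of least trimmed
squares in which the trimmed-subset size is not fixed in advance but
follows from the error bound β:

* **Annealing rounds.**  A residual threshold starts at `5β` and decays by
  a factor 0.7 per round until it reaches β exactly (≈ 6 rounds).  Each
  round intersects the active set with the spots whose residuals under the
  *current* fit are below the threshold, then refits and re-induces the
  indices.  Two details matter:
  * the candidate basis itself serves as the round-0 fit, so the first
    trim uses its residuals.  Fitting all spots first is unsafe on small
    frames — a 3×3 basis (9 parameters) fitted to 12 spots can absorb
    3 outliers entirely, leaving nothing above threshold;
  * active sets are nested (trim-only), which makes the trimmed loss
    provably non-increasing across rounds by the standard concentration
    argument, and empirically non-increasing under index re-induction.
* **Convergence at β.**  Once the threshold reaches β, spots consistent
  with the refined fit may re-enter; fit/trim rounds repeat until the
  inlier set reproduces itself (bounded iteration count).
* **Local repair.**  The fixed point is a local optimum of the trimmed
  loss.  A bounded search — re-admitting single spots just above the
  threshold, and restarting the β fixed point with each single inlier left
  out — lets a wrongly captured outlier be displaced by the spots it was
  masking.  States compare by (cardinality, then loss).  On frames of
  ≤ 12 spots this search makes the returned inlier set coincide with an
  exhaustive optimum over all subsets whenever that optimum is unique.

If at any point fewer than `k_min` spots survive, or the surviving indices
span rank < 3 (a planar assignment cannot determine a 3-D basis), the
candidate yields no solution rather than a regularised guess.

## Parameters

| name | default | meaning |
|---|---|---|
| `lattice_size` | 50 000 (full) / 10 000 (rt) | sphere samples per axis |
| `angle_resolution` | 150 / 100 | spin snapshots per 360° |
| `num_top_solutions` | 400 / 25 | bases passed to robust fitting |
| `num_top_vectors` | 64 | vectors kept per axis after ranking |
| `max_error_beta` | 0.002 Å⁻¹ | inlier residual bound β |
| `min_spots_kmin` | 10 | minimum inliers for a valid solution |
| `max_spots` | 80 | fixed per-frame spot count for batching |
| `max_lattices` | 2 | solutions reported per frame |
| `length_tol` / `angle_tol` | 0.05 / 3° | cell-shape acceptance window |

The "full" and "rt" presets are the two published operating points of the
sampling stage; "rt" trades sampling density for speed.  β and `k_min` are
data-quality judgements: β ≈ 0.002 Å⁻¹ corresponds to sub-millimetre peak
accuracy at typical protein-crystallography geometries, and `k_min = 10`
spots comfortably over-determines the 9 basis parameters.
`num_top_vectors = 64` keeps the phase-2 basis count
(3 · 64 · `angle_resolution`) tractable while preserving coverage: for a
noise-free frame at rt sampling at least one retained basis induces ≥ 80 %
correct indices (asserted in the tests).

## Synthetic frames

The simulator draws a Haar-uniform rotation per crystal, enumerates the
reciprocal lattice points with |s| ≤ `s_max` (default 0.35 Å⁻¹) lying
within a slab of half-width `slab_width` (default 0.003 Å⁻¹) around the
Ewald sphere — the slab stands in for mosaicity/bandwidth making
reflections observable — samples the requested number of them, adds
isotropic Gaussian positional noise, and replaces a fraction with uniform
outliers drawn from the same slab shell (geometrically plausible false
peaks).  Orientations, Miller indices, inlier labels and per-crystal ids
are recorded exactly, so the simulator is the ground-truth oracle for
every downstream test.  When a detector projection is requested, spots are
first snapped onto the Ewald sphere (a detector position determines the
scattered-ray direction, hence a reciprocal vector exactly on the sphere),
making the detector → reciprocal round trip exact; in that mode the
snapping distance (≤ `slab_width`) adds to the effective inlier error.

What the simulator does *not* model: intensities and partiality, detector
point-spread and gaps, beam divergence/bandwidth profiles, and correlated
peak-finding errors.  Passing tests therefore demonstrate the geometric
and statistical core of the method — orientation recovery under positional
noise and uniform false peaks — not end-to-end performance on real images.

## Numerical choices and conventions

* Lab frame: right-handed, beam along +z, flat detector ⊥ z at +distance;
  pixel coordinates 0-based at pixel centres, mm = pixel × pixel size.
  Internal units are Å / Å⁻¹; nm⁻¹ appears only in the stream-style
  writer (conversion ×10).
* Canonical `B₀`: real a along +x, b in the xy-plane, right-handed.
* Index rounding: componentwise, ties to even.
* Singular/degenerate guards: singular candidate bases score −∞ in
  ranking; rank-deficient Miller matrices abort the candidate.
* Solution identity: a lattice basis is recoverable only up to an integer
  unimodular change of basis, so tests compare `Ã U` against the truth
  over all U with entries in {−1, 0, 1} and |det U| = 1 (a wider entry
  range is available for strongly sheared cells).

## Verification problem sizes

The statistical checks run on synthetic frames of 40 spots (60 for
two-crystal frames) from a 40 × 45 × 50 Å orthorhombic cell at λ = 1 Å,
with noise σ = 0.25 β and 20 % outliers, using the rt preset with
`lattice_size` reduced to 2000 — sampling densities chosen so the whole
verification suite completes in minutes on one CPU core while leaving the
method's accuracy regime unchanged.  The exhaustive-subset comparison uses
12-spot instances with 3 outliers and `k_min = 6`, where full enumeration
is feasible.

## Known limitations

* Single flat-panel detector geometry only; no multi-panel or curved
  detectors, no detector distortion refinement.
* Unit-cell parameters must be known in advance; the method validates
  shape but does not search cell space.
* Centring (P/C/I/F/…) is carried as metadata; no systematic-absence
  logic is applied to induced indices.
* The greedy multi-lattice rule (inlier overlap < 50 %) resolves a small
  number of well-separated lattices; heavily overlapping lattices are out
  of scope.
* No gradient-based or per-spot anisotropic refinement of the final basis.
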