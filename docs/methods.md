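# Methods

## Scope and data model

`pulsepore` couples a chemometric regression layer (PLS on pulse-condition
sample tables) with geometric analytics on particle configurations of
hydrated bilayers. A sample table row is one pulse condition — width (ns),
field strength (kV/cm), YP-positive %, PI-positive %, fusion % — with a
`train`/`test`/`unassigned` role. A particle frame is positions (nm),
per-particle charges (e), species labels, and an orthorhombic periodic box;
coordinates are wrapped into [0, L) on load. Frames come from PDB/GRO files
(via MDAnalysis, with charges supplied by a label→charge map because neither
format carries them) or from a native columnar text format whose float
round-trip is bit-exact.

## PLS regression

Predictors and response are mean-centered and scaled to unit sample standard
deviation (n − 1 denominator) before fitting; this preprocessing choice
reproduces the shipped reference table's predicted-fusion column and yields
a unit-norm weight vector (0.52² + 0.86² ≈ 1). Components are extracted by
NIPALS with deflation of X by t·p′ per component. The inner iteration
converges in one pass for a single response, where the first weight vector
is the normalized cross-covariance X′y/‖X′y‖; the loop is retained so the
path extends to multi-response data. Weight vectors are sign-oriented so the
largest-magnitude entry is positive — predictions are invariant to this
choice. Prediction collapses the sequential deflation into the single linear
map B = W(P′W)⁻¹C′ on scaled predictors. With as many components as
predictors, PLS training predictions coincide with ordinary least squares;
the test suite asserts this against a closed-form OLS solve and
cross-checks the full path against scikit-learn's PLSRegression.

Missing values are rejected with an error naming the column; the default
component count is 1 throughout (one latent dimension carries most of the
predictor covariance in this design). "Held-out R²" is ambiguous in the
field, so both standard definitions are always reported side by side:
1 − SSres/SStot about the held-out mean, and the squared Pearson
correlation of predicted vs observed. On the reference table's four test
rows these give 0.670 and 0.749 respectively — materially different, which
is why neither is silently preferred.

## Validation protocols

*Repeated splits.* Each of n_repeats (default 500) repeats draws a uniform
random partition without replacement at a 2:1 train:test ratio (8:4 for 12
samples) and refits the full pipeline, scaling included. Partitions are
drawn over sorted sample ids so results do not depend on the row order of
the input table. Splits whose training response has zero variance are
recorded as failed and excluded, with a logged count.

*Leave-one-out Q².* Q² = 1 − PRESS/SStot with a full refit (rescaling and
model) per fold. Q² of pure noise is negative in expectation because PRESS
exceeds SStot; the suite verifies this on seeded noise and checks the
implementation against an independently coded fold loop.

*Y-scrambling.* The model is refit on seeded random permutations of the
response; each record stores the Pearson correlation between permuted and
original response plus the refit R² and Q². The identity permutation is
always record 0. The trend summary is the Spearman rank correlation between
|y-correlation| and R² across records: positive when model quality
genuinely tracks the response rather than arising by chance.

*Randomness.* One integer seed per run; per-repeat sub-streams are derived
from (seed, repeat index) with numpy's SeedSequence semantics, so results
are reproducible and independent of execution order.

## Membrane electrostatics

The charge density ρ(z) sums per-particle charges in uniform slices
(default 0.1 nm) and divides by slice volume; the profile integral always
recovers the total frame charge. If the bin width does not divide the box
edge to one part in 10⁶, the grid stops short and particles beyond the last
edge are counted into the last bin with a logged warning (uniform bins are
an invariant of the profile container). The potential is the double
cumulative integration of ρ — two successive cumulative sums of bin value ×
bin width, exact for piecewise-constant densities — in reduced units
(ε₀ = 1, charge in e, length in nm) with φ = 0 at the lower box edge.
Converting to volts is presentation, not computation, and is left to the
caller. No periodic (tin-foil) or dipole correction is applied: for a frame
with a net dipole the potential at the two box edges differs, and this is
accepted rather than corrected. The transmembrane potential Δφ is the mean
potential over an upper bulk-water z-interval minus that over a lower one;
regions overlapping the membrane slab are rejected when leaflet bounds are
supplied.

Leaflet planes are estimated by a 1-D two-means split of headgroup z
coordinates (Lloyd iterations initialised at the z extremes). A frame whose
headgroups collapse onto one layer — separation below 0.5 nm — raises an
error advising manual bounds, since a pore-collapsed or single-sheet
configuration has no meaningful leaflet split.

## Pore metrics

The inter-leaflet water count converts to volume with a configurable
per-molecule constant, default 0.030 nm³ (ambient liquid water); the
synthetic generator places water at the matching 33.3 nm⁻³, so recovery
tests are self-consistent. Pores are resolved by binning core water onto a
2-D x–y occupancy grid (cell counts rounded so the grid tiles the periodic
box exactly) and labeling occupied cells by connected components with
4-neighborhood connectivity and periodic wrap — 4-connectivity is the
conservative choice that avoids diagonal bridging of distinct pores.
Components below `min_cells` (default 2) are discarded as single-cell
noise. Only the central 50 % of the inter-leaflet gap is considered by
default so headgroup-adjacent water does not trigger false pores. Pore
centroids are periodic (circular) means, always inside the box. Pores are
counted independently per frame; no identity tracking across frames is
attempted. Tests cross-check the periodic labeling against an independent
oracle: the component count is invariant under cyclic rolls of the grid,
and for components smaller than half the box some roll clears the grid
edges, where a plain flood fill is correct.

Grid resolution matters through water sampling: cells much smaller than the
inter-water spacing (~0.3 nm at ambient density) fragment the occupancy
mask. The stability tests therefore refine from 0.5 to 0.25 nm cells on a
1.5 nm pore (three cells across at the coarse grid), where the recovered
area moves by well under 10 %.

## Synthetic data

*Bilayer frames.* Pseudo-lipids — a ±q head-charge pair at ±0.05 nm about
the leaflet plane plus three neutral tail beads at 0.25 nm spacing toward
the midplane — on a square lattice with Gaussian positional jitter (default
sd 0.03 nm). The default geometry is an 8×8×10 nm box with leaflet planes
at 4.0 and 7.0 nm, 256 lipids per leaflet, and bulk water at 33.3 nm⁻³ on
both sides. These are not chemically realistic lipids: every metric under
test depends only on charge/label/position geometry, so one charge pair and
a few beads suffice. Planted pores remove the lipids inside a cylinder and
fill it with water at bulk density; overlapping pores are rejected. Net
frame charge is exactly zero by the ± pairing. The ground-truth record
(leaflet planes, pore centers/radii, water counts) is what the parameter-
recovery tests compare against.

*Charged slabs.* Two uniformly scattered sheets of point charges with
surface densities +σ and −σ at (Lz ∓ d)/2. Per-particle charge is
σ·Lx·Ly/n, so the planted density is exact at any discretization. The
parallel-plate closed form |Δφ| = σ·d is the oracle for the potential path.
With the +σ sheet below, Δφ itself is −σ·d; monotonicity checks are made
on the magnitude.

*PEF response tables.* The generative chain mirrors the experimental
narrative: pore number N = a_N·max(0, E − E_th) rises with field strength
above a threshold (defaults a_N = 2 per kV/cm, E_th = 0.2 kV/cm); the
large-pore fraction S = logistic(a_S·(log₁₀ w − 3.5)) rises with pulse
width; YP saturates on N and PI on N·S through the shifted logistic
100·(2·logistic(k·x) − 1), which is 0 at zero dose and saturates at 100 %
(k_y = 0.6, k_p = 0.55 put the strongest condition near 87 % YP / 80 % PI,
matching the scale of the reference table); fusion is
β₀ + β_small·yp + β_large·pi with β_large = 0.12 > β_small = 0.02, making
the large-pore channel dominant by construction. Gaussian noise (sd 3 % on
the dye rates, 0.5 % on fusion, the scale of replicate scatter in such
assays) is added before clipping to [0, 100], which makes extreme-dose rows
heteroscedastic — documented, not corrected. The default grid is 7
strengths (0–2.4 kV/cm) × 4 widths (200 ns–40 µs), 28 rows.

Because fusion is exactly linear in (yp, pi) before noise, the noiseless
table is fit perfectly (R² = 1) at full rank; a single component reaches
R² ≈ 0.95, not 1, because the width-dependence of the PI channel makes the
two predictors imperfectly collinear — a deliberate feature of the preset,
since a one-dimensional latent structure with exactly collinear predictors
would be a degenerate test of the regression.

What the generators do **not** emulate: water structure and hydrogen
bonding, lipid conformational dynamics, field-driven pore nucleation and
growth, membrane undulations, or any force-field energetics. Passing tests
show that the *metrics* recover planted geometric and statistical ground
truth at realistic sizes and noise levels; they say nothing about the
behaviour of real simulated membranes beyond that.

## Problem sizes

The shipped analyses run at the scale the package targets: 12-sample
tables, 500-repeat split validation and 500-permutation scrambling (a few
seconds each), and synthetic frames of ~15 000–20 000 particles (256
lipids/leaflet plus ~1 900 waters per nm of bulk slab), at which every
profile and pore metric completes in well under a second per frame.

## Known limitations

- Single-response PLS only; multi-block variants, variable selection and
  coefficient confidence intervals are out of scope.
- The potential profile reports reduced units; no SI conversion is asserted
  anywhere because the ε₀ = 1 convention does not commute with volts
  without an extra, application-specific constant.
- Pore detection is a 2-D occupancy surrogate: tilted or toroidal pore
  shapes are summarised by their x–y footprint, and pores narrower than
  about two grid cells are not resolved.
- Binary trajectory formats (XTC/TRR) are not read; frames arrive as
  PDB/GRO/native text.
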