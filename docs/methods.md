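# Methods

This note records the models and procedures implemented in `pipnano`, the
assumptions behind them, the defaults that matter, and what the synthetic
generators do and do not emulate.

## Scope and data model

The package analyzes coarse-grained (Martini-style) membrane snapshots in
which each lipid is a short string of named beads (NC3, PO4, GL1, C1A, ...).
A snapshot (`Frame`) is an orthorhombic periodic box plus beads grouped
into lipids; a species map (`LipidTopology`) declares each species'
headgroup beads, phosphodiester bead (PO4), glycerol-proximal anchor, and
ordered acyl chains. Stock topologies cover POPC and three PI(4,5)P2
acyl-chain variants (di-16:0, di-18:1, and 18:0/20:4), written to
coordinate files under the residue names POPC, DPP2, DOP2 and SAP2.

All coordinates are held in nanometres. Only orthorhombic boxes are
accepted: triclinic input raises immediately rather than being silently
sheared, since every cutoff-based analysis here assumes rectangular
minimum-image geometry. GRO files (fixed-column, nm, concatenated frames
allowed) and PDB files (ATOM records, Angstrom converted on load,
multi-MODEL allowed) are parsed natively so that format errors can cite
the offending line. On load, each lipid is made whole under minimum image
before any analysis.

### Leaflet assignment

Lipids are assigned to leaflets by the sign of their reference-bead
(default PO4) height relative to the bilayer mid-surface. For flat
membranes this is the global mean reference height. When the lateral
variation of the local mid-surface (cell-mean reference height on a
~3 nm grid) exceeds half the apparent monolayer thickness, the grid-local
midplane is used instead, so lipids on the flanks of a strong undulation
are not misassigned. If the reference beads all sit within one thermal
width (default 0.5 nm) of the midplane — a monolayer, or a collapsed
geometry — assignment raises a degenerate-geometry error instead of
guessing. How leaflets should be assigned in strongly undulating
asymmetric membranes is genuinely open; the grid-local rule is this
package's choice and both thresholds are exposed.

## Cluster analysis

Two lipids of the clustered species are adjacent when **any pair of their
selected beads** lies within the contact cutoff under minimum image;
clusters are connected components of this graph. Defaults: cutoff 0.6 nm,
headgroup beads only (inositol ring, ring phosphates, PO4), and in-plane
(x,y) distances, because the clusters of interest are leaflet-lateral
objects. All three choices are exposed because reasonable alternatives
exist and no single convention is canonical; the cutoff sits just beyond
the first-neighbour shell of coarse-grained headgroups. Divalent cations
never enter the adjacency definition even when present: clustering is
defined purely lipid–lipid, with cation bridging implicit in the geometry.

One consequence of in-plane adjacency worth knowing: in a *symmetric*
bilayer, lipids from opposite leaflets that happen to coincide laterally
can merge into one cluster. This is intended behaviour for nanodomain
analysis (a trans-bilayer stack is one lateral object), but the dispersed
"every lipid is a monomer" limit is only guaranteed in systems where the
species occupies a single leaflet.

Average cluster size is reported with both conventions, labelled:

- number-weighted: (sum of sizes) / (number of clusters), monomers included;
- mass-weighted: (sum of sizes squared) / (sum of sizes).

The number-weighted value is the headline default. Trajectory series
re-run detection per frame and assert size conservation every frame.

The detector is a KD-tree pair search with periodic boxing plus
union-find; the test suite holds it to exact agreement with a brute-force
O(N^2) enumeration over all periodic images on hundreds of random frames.

## Acyl-chain order

The S-value of a chain bond is the second Legendre polynomial of the
angle between the bond and the membrane normal,

    S = (3 <cos^2 theta> - 1) / 2,

so S = 1 for bonds along the normal, -0.5 for in-plane bonds and 0 for
isotropic orientations. The normal is the global z axis, signed per
leaflet; since only cos^2 enters, profiles are leaflet-symmetric by
construction. Per-bond standard errors propagate the sample variance of
cos^2 through the Legendre form. Using the global normal assumes the
membrane is kept flat (as when undulations are restrained); for strongly
curved surfaces a local-normal variant would be needed and is not
implemented.

Distance-resolved order (the "how far does a nanodomain's influence
reach" analysis) assigns each probe lipid the in-plane minimum-image
distance from its glycerol-proximal anchor to the nearest bead of any
reference-species molecule in the same leaflet — molecule-level nearest,
not bead-averaged — and pools the first bond of every probe chain into
half-open distance bins (default 0.2 nm wide out to 3 nm, the range over
which such perturbations decay). Empty bins are reported as missing
(NaN), never as zero; pooling every bin reproduces the unconditioned
first-bond S exactly, a conservation property the tests assert.

## Hexagonality (gel hallmark)

Gel-phase chains pack on a triangular lattice, so each interior chain has
six neighbours spaced 60 degrees apart in azimuth. Each acyl chain is
reduced to its in-plane centroid; a chain is counted as hexagonal iff

1. at least `min_neighbors` (default 6) centroids lie within
   `neighbor_cutoff` (default 0.55 nm, between the 0.48 nm gel lattice
   pitch and typical fluid chain spacings), and
2. the six nearest of those, sorted by azimuth, have all consecutive
   gaps (wrap-around included) within 60 +/- `angle_tolerance` degrees
   (default 15 degrees, wide enough that ~10% thermal jitter of a gel
   lattice still classifies).

The count is exactly the interior of a perfect lattice patch: a compact
127-chain triangular disc yields 91 hexagonal chains (the next centered
hexagonal number down), which the tests assert together with invariance
under in-plane rotation and monotonicity in the angular tolerance. The
criterion deliberately mirrors a lattice-membership count rather than the
psi-6 bond-orientational order parameter, which measures a related but
different quantity. Whether chains or lipids are counted is a convention;
chains are counted here and every threshold is recorded in the result.

## Surfaces: height, thickness, curvature, registration

Leaflet surfaces are gridded (default 1 nm cells, periodic) from the
reference-bead heights; cell height is the mean over contributing beads.
Thickness is the upper-minus-lower height per cell, masked where either
leaflet is absent, reported alongside per-species mean heights per
leaflet (the quantity behind lipid-height-difference observations, e.g. a
planted gel patch standing 1 nm proud of the fluid background).

Local mean curvature is estimated by least-squares fitting the quadratic
Monge patch z = a x^2 + b y^2 + c xy + d x + e y + f to the occupied
cells within `fit_radius` (default 2.5 nm) of each cell and evaluating

    H = (a (1 + e^2) + b (1 + d^2) - c d e) / (1 + d^2 + e^2)^(3/2).

The first-fundamental-form correction is always applied, so arbitrarily
tilted planes are exactly flat — a property the tests check to 1e-6 /nm.
**Sign convention (upward normal):** a crest or dome (local bump toward
+z) has H < 0; a bowl or valley has H > 0. Every CLI output header states
this. Rank-deficient fits and values beyond the grid Nyquist-like bound
|H| <= 1/(2 spacing) are masked, not raised.

Two numerical facts matter in practice. First, the quadratic fit
attenuates curvature that varies over the stencil: for a 25 nm
undulation sampled at 1 nm with a 2.5 nm fit radius the crest estimate is
biased low by roughly 2%. Second, single-snapshot bead jitter dominates
the error; surfaces should be averaged over frames before
differentiating, exactly as one would average over trajectory frames.
The validation suite averages 12 independently seeded realizations of the
planted sinusoid (A = 1 nm, L = 25 nm, ~2000 lipids), which brings the
crest estimate within 5% of the closed form A (2 pi / L)^2 / 2 =
0.0316 /nm; a synthetic spherical cap (R = 10 nm) reproduces 1/R to the
same tolerance.

Inter-leaflet registration of a species is the Pearson correlation of its
two per-leaflet binary occupancy fields (default 2 nm cells): +1 for
registered domains, ~0 for independent placement, negative for
anti-registration. Pearson on occupancy was chosen over overlap-area
fractions because it is bounded, symmetric under leaflet exchange and
zero-centered under independence; the grid spacing is a sensitivity
parameter and is recorded in the result. Registration is undefined — and
raises — when the species occupies only one leaflet.

## Fluorescence computations

Steady-state anisotropy follows the standard two-polarizer scheme:

    <r> = (IVV - G IVH) / (IVV + 2 G IVH),      G = IHV / IHH.

Anisotropy and G are invariant under overall intensity scaling. For
non-negative intensities r is confined to [-0.5, 1]; blank
over-subtraction can push components slightly negative, in which case an
out-of-range r is flagged with a warning and returned unclamped.

TCSPC decays are modelled as delta-excitation sums of exponentials
i(t) = sum_i alpha_i exp(-t / tau_i) with normalized amplitudes. No
instrument-response deconvolution is performed: the synthetic generator
and the fitter share the same delta-excitation assumption, so the pair is
self-consistent, and the conventional reduced-chi-squared acceptance
bound of 1.3 is adopted as the fit-quality criterion in this setting.
Fitting minimizes Poisson-weighted squared residuals (weights
1/max(counts, 1); the floor keeps empty tail channels finite) of the
**channel-integrated** model using Levenberg–Marquardt. Multi-exponential
fits are initialization-sensitive, so the fitter restarts from a
log-spaced grid of lifetime combinations — amplitudes seeded by
non-negative linear least squares at each candidate — and keeps the
lowest reduced chi-squared. Amplitudes are renormalized to sum to one and
components returned in increasing-lifetime order; lifetimes converging
onto their box bounds are flagged as unidentifiable. Diagnostics include
the weighted residual trace and its autocorrelation: a misspecified model
(one exponential fit to two-component data) is visible both as chi2 well
above 1.3 and as strongly structured residual autocorrelation. The
amplitude-weighted mean lifetime is tau_bar = sum_i alpha_i tau_i.

Thermal scans of anisotropy are fit with a symmetric logistic

    r(T) = r_low + (r_high - r_low) / (1 + exp((T - Tm) / w)),

where r_high is the low-temperature (ordered-phase) plateau and Tm the
transition midpoint. A melting transition is reported only when the
fitted amplitude exceeds three times the residual standard deviation
*and* the fitted width is below a quarter of the sampled span; the width
criterion is what rejects broad quasi-linear drifts, which a wide
logistic can otherwise fit with deceptively small residuals. A midpoint
outside the sampled range is flagged unreliable (extrapolation). The
model family had to be pinned for reproducibility; a midpoint is only
well-defined relative to a declared parametric family.

## Synthetic generators: what they emulate, and what they do not

Every generator takes a seed, is bit-for-bit reproducible, and records
its planted truth (partitions, gel membership, analytic curvature, decay
components, melting midpoint). The central contract, exercised end to end
by the tests, is that each planted structure is **exactly recoverable**
by the corresponding analysis whenever the stated separations hold (e.g.
cluster gap > detection cutoff > intra-cluster spacing).

Membranes are geometric constructions, not simulations: two mirrored
leaflets on jittered square lattices (default 0.64 nm^2 per lipid, a
typical fluid coarse-grained value), with chains grown bead by bead
toward the midplane at 0.47 nm per bond. A single `chain_disorder` dial
d in [0, 1] draws each bond's polar cosine uniformly from [1 - 2d, 1],
giving exactly straight chains at d = 0, isotropic bonds at d = 1, and
the closed-form first-bond order S(d) = (b + b^2)/2 with b = 1 - 2d in
between (default d = 0.25, S ~ 0.375, a fluid-membrane-like value).
Planted clusters are compact triangular disks (pitch 0.45 nm) separated
by a guaranteed gap; gel patches are compact triangular-lattice discs of
straight chains at 0.48 nm pitch, raised by a planted height offset
(default 1 nm) above the fluid background, with intruding fluid lipids
relocated out of the patch footprint; undulations displace both leaflets
by A sin(2 pi x / L) with the exact curvature field recorded; asymmetric
bilayers place PI(4,5)P2 in the lower leaflet only and balance leaflet
areas through per-species area-per-lipid counts (mismatch under 1%).

What the generators do **not** emulate: thermodynamics. There are no
energies, no correlated fluctuations between neighbouring lipids, no
spontaneous phase transitions, no cation dynamics — structure is planted,
never emergent. Passing tests therefore demonstrate that the analysis
operators measure what they claim to measure on configurations of known
structure; they do not validate any claim about how real membranes
behave. Likewise the TCSPC generator draws independent Poisson counts per
channel under delta excitation (no instrument response, no afterpulsing,
no background), and the thermal-profile generator is the same logistic
family the fitter assumes plus Gaussian noise — parameter recovery there
checks estimator correctness, not model adequacy for real probes.

## Problem sizes and determinism

The validation suite runs on hundreds-to-thousands-of-lipid frames
(300-lipid frames for the brute-force cluster oracle, 512 for gel
patches, ~2000 for undulations, 10^6-photon decays, 21-point thermal
scans) — sizes chosen so each planted effect is measured with comfortable
statistical margin while the whole suite completes in about a minute and
a half on one core. All randomness flows through explicit integer seeds
(NumPy `default_rng`); there is no hidden global state.

## Known limitations

- Order parameters use the global z normal; curved or vesicular
  geometries are out of scope.
- In-plane cluster adjacency can merge laterally coincident lipids from
  opposite leaflets in symmetric bilayers (see above).
- The decay fitter assumes delta excitation; histograms convolved with a
  real instrument response will show biased short-lifetime components.
- Registration is a grid-occupancy correlation; its magnitude (not its
  sign) depends on the grid spacing, which is therefore always reported
  next to the coefficient.
- Triclinic boxes and compressed binary trajectory formats are
  deliberately unsupported.
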