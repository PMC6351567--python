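# Methods

## Model

Polymers are Kremer–Grest bead–spring chains in reduced units: bead size
σ (= a), energy ε, mass m, time τ = σ√(m/ε), temperature kBT = 1 ε.
Adjacent beads interact through the FENE potential

    U_FENE(r) = −(1/2) k r0² ln[1 − (r/r0)²],   k = 30 ε/σ², r0 = 1.5 σ,

and *all* bead pairs — bonded neighbours included — repel through the WCA
potential (truncated–shifted Lennard-Jones, cutoff 2^{1/6} σ). The
combination places the mechanical bond minimum at r ≈ 0.961 σ and the
thermal mean bond length at ⟨b⟩ ≈ 0.97 σ, which every geometric template
in the package uses as its bead spacing.

Semiflexible chains add a harmonic bending term on each triple of
consecutive backbone beads,

    U_bend = k_b (θ − π)²,

with θ the interior angle at the middle bead (π for a straight chain).
The bending constant maps to a persistence length through
ℓp = 2 k_b ⟨b⟩ / kBT; this is the small-fluctuation limit of the
tangent-correlation decay and is accurate to ~2 % for ℓp ≳ 5 σ (exact
quadrature of ⟨cos θ′⟩ for ℓp = 10 σ gives 10.17 σ).

Bottle brushes — the coarse-grained stand-in for a supercoiled bacterial
chromosome, whose plectonemic loops act as side chains on a backbone —
have a fully flexible backbone of N beads (linear or ring) with a flexible
sidechain of Ns beads grafted to every backbone monomer, N(Ns+1) beads in
total, and no bending term: their effective stiffness is emergent,
controlled by Ns.

Confinement is a cylinder along z realized as smooth surfaces: the wall of
radius D/2 and, when closed, two flat pistons, each repelling beads
through the WCA form evaluated on the bead–surface distance. This is the
uncorrugated equivalent of a wall tiled with σ-sized beads: same range,
same stiffness, and beads can never cross a surface because the potential
diverges on it.

## Dynamics

Velocity Verlet with an impulse-style Langevin thermostat: at each step a
Gaussian random force with variance 2γmkBT/Δt per component is drawn once
and applied in both half-kicks together with the friction −γmv evaluated
at the current velocity. Defaults Δt = 0.005 τ, γ = 1 τ⁻¹, T = 1. γ = 0
degenerates to plain NVE velocity Verlet (energy drift < 1e-4 ε over 1e5
steps for a dimer at Δt = 0.001 τ); at γ = 1 the thermostat reproduces
equipartition to well under 1 %.

Pair sums use a Verlet neighbour list (cutoff + 0.4 σ skin, rebuilt
whenever any bead has moved more than half the skin; rebuilds are O(N²),
which is the right trade-off at these system sizes). Integration is
compiled with numba; trajectories are bit-reproducible for a fixed seed on
a given platform, and every replica draws an independent seed stream
derived from the base seed.

Failure is never silent: a FENE bond reaching r0, a bead at a confining
surface, or a non-finite energy aborts the run with the step index and the
last valid frame attached to the exception.

## Protocols

Semiflexible runs start from a straight line (or a serpentine path when
the chain is longer than the target cylinder), are capped by pistons 2 σ
beyond the chain, compressed at constant piston speed (default 1e-3 σ/τ,
both pistons moving symmetrically — the symmetric choice preserves the
mid-plane symmetry of the problem) until the gap reaches the target L,
equilibrated, and only then sampled.

Brush runs start from a helical backbone template with all sidechain beads
collapsed onto their anchors (0.05 σ jitter), inflate the overlaps with
the soft pair potential A[1 + cos(πr/r_c)] ramped linearly 0 → 60 ε over
the inflation stage (r_c = 2^{1/6} σ), switch to WCA, then cap, compress,
equilibrate, produce. Because opposite helicity states of a confined
brush are separated by a barrier that is insurmountable on simulation
timescales, production sampling is *local-equilibrium* sampling of the
sub-ensemble selected by the initial handedness; the population
distribution is the equal-weight sum of the left and right sub-ensemble
distributions. A persistent sign change of the writhe smoothed over 50
samples lasting more than 100 samples is logged as a handedness flip —
detected and recorded, never assumed away.

Helical templates: the helix radius is D/2 − 1.5 σ and the number of turns
is chosen so the template writhe magnitude falls in the 1–2 band of the
helically organized states; when no turn count at the full radius reaches
that band the radius is reduced stepwise (this happens for wide cylinders).
Handedness of a *state* is identified with the sign of Wr (left ⇔ Wr < 0),
matching how the sub-ensembles are labelled. For a linear polymer the
template winding sense and the writhe sign coincide. A ring is folded into
two antiparallel arms that spiral together along the wall; the crossings
between antiparallel arms dominate the Gauss sum with a sign *opposite* to
the arms' winding sense, so the construction picks the winding that
delivers the requested writhe sign and verifies it on the built template.
Left and right initial states are exact mirror images.

Every stage is bookkept (step boundaries, seeds, piston positions) in a
manifest sufficient to re-run bit-identically; production trajectories
contain no compression frames.

## Writhe

For a polygonal curve, the Gauss double integral reduces to a sum over
non-adjacent segment pairs of the exact signed solid angle of the pair:
the quadrilateral cut on the unit sphere by the directions between the
segment endpoints, evaluated as two spherical triangles with the
numerically stable atan2 form 2 atan2(a·(b×c), 1 + a·b + b·c + c·a); the
traversal orientation carries the crossing handedness. (The equivalent
arcsine form of the same quadrilateral area is ill-conditioned when
segments pass close to each other and was rejected for that reason.)
Adjacent pairs share a vertex, are coplanar, and contribute exactly zero.
Open chains use the same double sum without artificial closure — the
standard open-chain writhe, and the only reading consistent with reporting
Wr for linear polymers. The test suite holds an independent brute-force
adaptive Gauss–Legendre quadrature of the double integral as the oracle;
the closed form agrees with it to near machine precision across all
fixture families, and is invariant under rigid motions and uniform
scaling to ~1e-14.

Sign convention: a right-handed helix (advancing +z while rotating
counterclockwise viewed from +z) has Wr > 0; mirror reflection negates Wr
exactly (bit-exactly for coordinate-plane mirrors, by symmetry of the
construction). Note two geometric consequences worth keeping in mind when
interpreting signs: closing a solenoid through its own axis threads the
coil and reverses the sign relative to the bare winding sense, and a
folded ring (two antiparallel arms on one helical track) likewise carries
writhe of sign opposite to its winding sense.

Distributions: P(Wr) is a normalized histogram with bins centred on
Wr = 0 (default width 0.1), so mirror symmetry maps bins onto bins; the
free energy F = −kBT ln P is reported relative to its minimum on occupied
bins. Means and standard deviations are computed from the raw samples,
optionally with per-series weights (used for the equal-weight sub-ensemble
pooling regardless of sample counts).

Coarse-graining emulates finite experimental resolution: ``average``
replaces non-overlapping blocks of m consecutive vertices by centroids
(a partial final block is averaged as-is, with a warning), ``skip`` keeps
every m-th vertex. Sidechain tracking concatenates all sidechains root to
tip in backbone order and block-averages that path, giving
N·Ns/m vertices.

The integrated autocorrelation time of a series is defined as
1/2 + Σ ρ_k up to the first zero crossing of the normalized ACF, in units
of the sampling interval (so an AR(1) process with coefficient a gives
(1+a)/(1−a)/2, and white noise gives 1/2). Production runs shorter than
20 τ_int of the writhe are flagged under-sampled in their manifest.

## Chain observables

* ⟨b⟩: time-averaged bond length.
* Persistence length (projection estimator): the frame-averaged projection
  of the backbone end-to-end vector on the k-th unit bond vector,
  maximized over k (maximum of the mean profile, not the mean of maxima).
  This is the estimator used for bottle brushes, whose stiffness is
  emergent and has no k_b to read off. **Caveat:** for an ideal worm-like
  chain the projection at an *interior* bond sums orientational
  correlations towards both chain ends, so the maximum reads ≈ 2ℓp − b
  rather than ℓp (the chain-end value reads ≈ ℓp). The estimator is
  reported as defined, without rescaling; when a tangent-defined ℓp is
  wanted for a semiflexible chain, fit the bond-correlation decay instead
  (the suite does exactly that as an oracle and recovers 2k_b⟨b⟩/kBT
  within 15 %).
* Extension R_∥: mean of max(z) − min(z) over beads, meaningful in an open
  cylinder; L < R_∥ defines the compressed regime.
* Volume fraction: φ = n_beads (π/6) σ³ / (π (D/2)² L), counting each bead
  as a sphere of diameter σ. This convention is stated explicitly because
  φ conventions differ; the chromosome-like ring brush (N=200, Ns=10,
  D=18a, L=45a) sits at φ ≈ 0.10.

## Synthetic fixtures and what they do (and do not) show

`shapes` provides analytic curves with known or oracle-computable writhe
(planar circle: 0; planar hairpin: 0; helices and solenoids of either
handedness; a lifted figure-eight with a single signed crossing; seeded
random walks) and seeded Gaussian-mixture surrogates of the left/right
sub-ensemble writhe statistics. These exercise every analysis stage
without dynamics. The coarse-graining equivalence check uses helices
roughened with *correlated* vertex noise (iid noise smoothed over 5
vertices), emulating the short-wavelength thermal wiggle of a real
backbone; with strictly independent per-vertex noise, block-averaging
suppresses noise faster than decimation and the two resolutions are *not*
statistically equivalent — itself a useful reminder that resolution
effects depend on the noise spectrum of the measurement. Passing these
tests shows the analysis machinery is correct; it does not by itself show
that a given simulated ensemble is equilibrated, which is what the
autocorrelation guard and replica spread are for.

## Problem sizes used by the test suite

The full study conditions (1e8–2e8 steps per stage, 20 replicas, up to
~8200 beads) are cluster-scale; the package's own test suite reproduces
each qualitative claim at desk scale and ships the full-scale
configurations separately under `full_scale/`. The scaled runs used by
the suite are: the 25-bead free chain for the bond length (2e6 production
steps); N = 100, 5e6 steps in free space for the persistence estimators;
and the N = 25, D = 4a, L = 20a confinement scan at a ~100× reduced
schedule (8 replicas, 2e6 production steps each, piston speed 5e-3 σ/τ),
validated by requiring production ≥ 20 τ_int(Wr). At this scale the
stiff-chain (ℓp = 100a) writhe peaks sit at |Wr| ≈ 0.2 rather than the
deeper basins of the full runs — compression is mild (L/contour ≈ 0.86) —
but the qualitative signature under test (two opposite-sign maxima with a
depleted Wr = 0, versus a single central peak at ℓp = 32a) is robust.

## Known limitations

* No twist degree of freedom, no torsional potential, no linking number:
  helicity is measured purely by writhe.
* No hydrodynamic interactions; Langevin friction only.
* The desk-scale brush runs (short sidechains) do not show the kinetic
  handedness locking of the long-sidechain systems — the locking is a
  genuine large-Ns effect, so sub-ensemble sign stability is asserted only
  in the full-scale tier.
* Smooth walls: no corrugation-induced pinning.
* The projection persistence length reads ≈ 2× the tangent-correlation
  value on worm-like chains (see above); comparisons across estimators
  must use one convention.
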