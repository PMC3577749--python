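# Methods

This note documents the models implemented in `pepdimer`, the defaults
that matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was open.

## System and conventions

The package is organised around a two-chain peptide system: a linear
eleven-residue chain (chain A, author numbering 60–70, sequence
MSTYTGIFTDQ) and a cyclic chain (chain B, the same sequence flanked by
Cys59/Cys71; the disulfide is topological metadata only — no bonded-term
computation exists here).  Internal length unit is Å (PDB native); the
landscape module reports nm because extension/gyration plots are
conventionally drawn in nm.  "Backbone" means atom names {N, CA, C, O}.
Masses are standard atomic masses; van-der-Waals radii are the Bondi set.
k_B = 0.0019872041 kcal/mol/K, temperature default 300 K.

## Superposition and clustering

RMSD uses the Kabsch algorithm with the determinant correction that
excludes reflections; collinear or <3-point fits are rejected.  The fit
subset and measurement subset may differ.  Single-linkage clustering at a
cutoff is implemented as connected components of the strict threshold
graph (d < cutoff), which is mathematically identical to agglomerative
single linkage cut at that height and admits a trivially correct
union-find oracle, used in the tests.  Cluster ids are ordered by
population (ties by earliest frame); representatives are medoids (minimum
summed intra-cluster distance, ties to the lowest frame index) — a
defensible convention where no canonical choice exists.  The
cutoff-selection rule accepts the smallest candidate giving fewer than 10
clusters or a top-cluster share ≤ 30 %; if no candidate qualifies the
largest is used with a warning.  Note the rule's two branches are
individually permissive at the extremes (a huge cutoff trivially
satisfies the first, a tiny one the second); it is intended for candidate
scans in the physically sensible 1–3 Å range, and the shipped default is
the single candidate 2 Å.

## Hydrogen bonds

A bond is reported when donor–acceptor heavy-atom distance ≤ 3.5 Å and
the hydrogen–donor–acceptor angle ≤ 30°, the standard geometric criteria
for MD analysis; the package does not invent numbers beyond these
defaults and both are configurable.  Donors are backbone N–H plus a
shipped side-chain table (Ser OG–HG, Thr OG1–HG1, Tyr OH–HH, Cys SG–HG,
Asn/Gln amides); acceptors are backbone O/OXT plus side-chain
carboxylates, amide oxygens and hydroxyls.  Same-residue pairs are
excluded; covalently adjacent residues are left to the angle criterion,
which rejects them geometrically (i, i±1 backbone N···O pairs sit near
2 Å but at ≥45° H–N···O).  Bonds are keyed by donor group and acceptor
atom, so the two carboxylate oxygens of an aspartate give distinct keys.
If explicit hydrogens are absent the module degrades to distance-only
criteria with a logged warning — never silently.  "Persistent" means
present in ≥ 50 % of frames by default.

## Secondary structure

The classifier follows the DSSP electrostatic model: backbone H-bond
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond
iff E < −0.5.  Missing amide hydrogens are reconstructed at 1.01 Å along
the previous residue's O→C direction — for this classifier only, never
for the H-bond profiles.  Patterns: consecutive (i,i+n) turns give helix
codes (n=4 → H, 3 → G, 5 → I), antiparallel/parallel bridge patterns give
B, runs of bridges give E, turn interiors give T, else C, with priority
H>G>I>E>B>T>C.  Residue pairs closer than |i−j|=2 are excluded from
bond energies and bridges require |i−j| ≥ 3.  This is a stand-in for
dihedral-augmented assignment schemes; it is validated on ideal
templates only, and no claim is made that it reproduces any specific
published assignment on real structures.

## Landscape statistics

The ring-orientation statistic is the angle between the Cα→Cγ vectors of
the two aromatic residues (Tyr63, Phe67).  The histogram uses 41 bin
**centers** at multiples of 4.5° from 0° to 180° with nearest-center
assignment (exact midpoints go to the lower center): "41 bins of 4.5°
over 0–180°" is arithmetically inconsistent as bin *widths* (41 × 4.5° =
184.5°), and centers honor both the count and the interval.  The
same-side fraction counts angles strictly below 90°; exactly 90° falls in
the opposite-side class.  D_N–C is measured between the backbone N of the
first residue and the carbonyl C of the last (configurable); R_g is
mass-weighted over all atoms of the chain, the convention of standard MD
analysis suites.  Basin detection — smoothing by a 3×3 mean filter, local
maxima, merging of peaks closer than 2 cells, nearest-peak mass
assignment, and a 5 % population floor — is a deliberately simple,
fully deterministic reading of a landscape that is otherwise inspected by
eye; it is not a watershed algorithm.

## SASA and buried hydrophobic area

Shrake–Rupley with a fixed golden-spiral point set (960 points/atom by
default, no RNG), probe 1.4 Å.  Buried hydrophobic area of the dimer is
(SASA_A,h + SASA_B,h − SASA_AB,h)/2 over atoms of Met/Tyr/Ile/Phe
residues, clamped at zero; monomer terms are computed with the partner
chain deleted.  A contact-count definition of "hydrophobic contact area"
would be an alternative reading; buried SASA was chosen as the standard
interface measure.

## Umbrella sampling and WHAM

Windows carry harmonic biases ½k(ξ−ξ₀)².  WHAM iterates the standard
self-consistent pair from fᵢ = 0, pins the gauge at f₁ = 0, and declares
convergence when max|Δfᵢ| ≤ 10⁻⁶ kcal/mol between sweeps (configurable;
flagged, not raised, on failure).  Bin width defaults to 0.05 Å.  The
Boltzmann factor of the bias is **bin-averaged** by 8-point midpoint
quadrature rather than evaluated at bin centers; with stiff biases whose
samples sit far from their window centers, center evaluation alone
introduces errors of several tenths of a kcal/mol.  Empty bins are
reported as missing (NaN), never as zero; populated regions separated by
more than two empty bins raise an error naming the gap, and adjacent
windows sharing no bins trigger a warning.

Dissociation ΔG is the plateau of the min-normalized PMF: the longest
terminal run of bins, within the last 20 % of the sampled range, whose
slope magnitude stays within `slope_tol` (default 0.05 kcal/mol/Å).
Slopes are measured on a 0.5 Å moving average with a ±0.25 Å central
difference, sparse edge bins (<25 % of the median count) and the
smoothing-biased terminal bins are excluded — raw bin-to-bin differences
are dominated by counting noise at any realistic sample size.  Whether a
published ΔG was read at a plateau or at a fixed separation is generally
not stated; the plateau is this package's defined contract.

Recovery scoring (`pmf_rms_error`) aligns the constant offset and
restricts to bins with ≥50 pooled samples lying in the thermally
accessible range (reference PMF within 10 kcal/mol of its minimum).
Outside that range the reference slope exceeds what a 0.05 Å histogram
can resolve (βU′Δ ≫ 1) and no binned estimator is meaningful, so scoring
there would measure discretization, not the method.  The reference used
for comparisons is the bin-averaged Boltzmann integral of the analytic
potential — the exact large-sample limit of a histogram PMF.

## Interaction enthalpies

Pure bookkeeping over supplied total energies: E_i = E(complex) − E(A) −
E(B); per-cluster sample sd (n−1 denominator, 0 when n=1); sd_percent =
100·sd/|mean|, reported as missing when the mean is 0; the reference is
the cluster with the lowest mean E_i.  Producing the energies (e.g. by
DFT single points) is explicitly out of scope; the module is unit-agnostic
beyond labeling kcal/mol.

## Synthetic data

The generators define the conditions under which everything is tested.

*1D sampling.*  Metropolis chains with Gaussian proposals (step 0.25 Å)
target exp(−β(U + w)); 500 burn-in steps are discarded and the chain is
thinned (default 5, 10 for the dissociation dataset where window overlap
is marginal) so returned samples are close to independent — acceptance
rates sit in the 0.2–0.8 mixing band and are asserted there.  Window
ladders default to the study geometry: 26 windows, 0.5 Å apart (symmetric
about 0), k = 20 kcal/mol/Å², 5000 samples per window, per-window seeds
seed+i.  Analytic potentials: harmonic ½κx², the double well 2(x²−1)²
kcal/mol, and a parabolic well that is exactly flat beyond its width (so
the planted dissociation ΔG equals the well depth).  On the double well
the outer windows saturate against the steep walls (the biased minimum
sits near |x| ≈ 2.2 for every center beyond); this is expected physics
and those windows simply reinforce the wall statistics.

*Templates.*  Backbones carry N, H, CA, C, O per residue plus a CG
pseudo-atom on the two aromatic residues.  Extended (φ=−135°, ψ=135°) and
helical (φ=−57°, ψ=−47°) chains are built by ideal internal coordinates
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å — scaffolding constants, not
claims about real structures).  A requested end-to-end distance is
enforced exactly by rotating the arm past the middle Cα about a hinge
axis (root-found with Brent's method; unreachable targets fail loudly).
Hairpin and cyclic templates are idealized flat antiparallel ladders with
3.5 Å rise and 4.13 Å strand separation so that a planted backbone bond
has N···O = 2.9 Å with the hydrogen exactly on the donor–acceptor axis;
planted bonds must connect ladder partners (residue indices summing to
n−1 — the 60↔70 / 62↔68 / 64↔66 registry of a real β-hairpin), and
non-planted carbonyls/amides point away from the partner strand, so
detection recovers exactly the planted set.  Requested ring angles are
made exact by placing the two CG atoms in controlled directions
perpendicular to the CA–CA axis.  H-bond schedules move the acceptor
oxygen onto the ideal position in an exact-count random subset of frames
(persistence targets are exact, not Bernoulli draws) and park it 6 Å
out-of-plane otherwise.

*Ensembles.*  Frames are drawn from a template mixture (seeded
multinomial) with i.i.d. Gaussian coordinate noise.  The shipped
four-state dimer recipe (weights 0.4/0.3/0.2/0.1, σ = 0.3 Å, mutual
backbone RMSD ≥ 5 Å) emulates the dominant-state structure of a
heterodimer ensemble: two open linear conformers and two hairpin-like
ones bound at different faces and orientations of the cyclic peptide.

*What the generators do not emulate* — and hence what passing tests do
not show about real data: force-field energetics, solvent, thermal
backbone fluctuations beyond isotropic noise, correlated frame-to-frame
dynamics (frames are i.i.d.), realistic side chains beyond the CG
pseudo-atoms, and the slow conformational exchange that makes real
cluster populations hard to converge.  Tests demonstrate the estimators
are correct on data satisfying their assumptions, not that 2.8 µs of real
trajectory would be reproduced.

## Problem sizes

Default analysis and validation sizes were chosen so a full run completes
comfortably on one CPU: 200-frame ensembles for clustering (the all-pairs
RMSD matrix is the dominant cost), 100-frame profiles for persistence
statistics, 5000 samples per umbrella window.  All are parameters, not
limits.

## Known limitations

- Single linkage chains aggressively by design; no alternative linkage is
  provided (an average-linkage oracle exists only in tests).
- WHAM here has no autocorrelation correction, no MBAR, no bootstrap
  error bars; reported PMFs carry no uncertainty estimates.
- The secondary-structure classifier is not a full STRIDE/DSSP
  reimplementation and its bridge/ladder logic is validated on ideal
  geometry only.
- The cyclic template's "turn" is a chain break in space (the ladder ends
  are simply adjacent); geometric continuity of the turn is not modelled.
- Basin coordinates depend on grid registration at the half-bin level.
- The cutoff-selection rule is honored as stated; see the clustering
  section for its degenerate extremes.
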