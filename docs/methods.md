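# Methods

## Coordinates and conventions

All coordinates are carried in nanometres, times in picoseconds, energies
in kJ/mol (k_B = 0.0083144621 kJ/(mol K), T = 300 K unless stated). PDB
files are converted from/to Ångström at the I/O boundary. Residues keep
author (PDB) numbering throughout, so selections can be written against
published residue labels (Val233–Ala241, Gln46–Leu67, Ala48–Thr54,
Cys14–Ala16, Tyr151, Arg17, …). Alternate-location conformers are resolved
by keeping the highest-occupancy conformer — the preparation of the
underlying crystal structure does not specify a rule, so this common
default is our choice. Hydrogens are kept when present (the hydrogen-bond
criterion needs them); "heavy" selections exclude them by element, not by
name prefix. No periodic-boundary unwrapping is performed: inputs are
assumed whole-molecule, and a guard errors if any reference-point pair is
farther apart than half a declared box length.

## Collective variables

Two proteins contribute three mass-weighted backbone reference points
each: T1/B1 are whole-chain backbone centres of mass, T2/T3 and B2/B3 are
centres of short well-structured segments. Backbone means exactly
{N, CA, C, O} per residue; the carbonyl O is included (standard backbone —
the choice is ours, it shifts centres of mass negligibly). The six
coordinates are r = |T1−B1|, Θp = ∠(T2,T1,B1), Φp = ∠(T3,T2,T1,B1),
θo = ∠(T1,B1,B2), φo = ∠(T2,T1,B1,B2), ψo = ∠(T1,B3,B1,B2). Angles are
computed and stored in radians; CSV output can add degree columns, since
positional shifts of the intermediate are conventionally quoted as
"10° (0.2 rad)". Dihedrals use the IUPAC sign convention (clockwise
positive looking from the second to the third point), fixed here because
the quantity is convention-dependent; range (−π, π], with −π mapped to +π.
Degenerate geometry (coincident or collinear defining points) raises
rather than returning a value.

## Reduced dissociation model and the random-force protocol

The biasing protocol is implemented exactly as used for ligand-egress
simulations: a force of constant magnitude F (default 3500 kJ/(mol nm))
and random direction acts on the ligand; after every evaluation interval
(100 fs) the direction is kept if the ligand's centre of mass moved by
*strictly more than* 0.0025 nm over the interval, and redrawn uniformly on
the unit sphere otherwise; the run stops at a dissociation cutoff
(3.4 nm) or a 40 ns cap.

The system it acts on is deliberately reduced: a single Brownian particle
(the ligand body) on a radial free-energy landscape, receptor fixed at
the origin. The landscape is a sum of Gaussian basins plus half-harmonic
walls:

U(r) = −Σᵢ Dᵢ exp(−(r−cᵢ)²/2wᵢ²) + walls below 2.40 nm and above 3.60 nm.

Defaults (shipped in `profiles/trypsin_bpti.yaml`): bound basin at
2.65 nm (depth 180 kJ/mol, width 0.040 nm) and prebound basin at 2.85 nm
(depth 240 kJ/mol, width 0.050 nm); ligand mass 6500 amu and friction
10 ps⁻¹. These are calibration constants of the reduced model, chosen once
so that the protocol's qualitative phenomenology appears at the protocol's
own default values: at F = 3500 kJ/(mol nm) most seeds dissociate within
the 40 ns cap after ≥ 1 ns dwells in the 2.75–3.00 nm band, at F = 0
nothing escapes the bound basin, and from roughly 5000–5500 kJ/(mol nm)
upward the intermediate is traversed too fast to register — the same
force-limit behaviour the atomistic system shows. The well depths are far
larger than k_BT because, as in the atomistic complex, escape is driven by
the applied force, not by thermal activation.

Propagation is overdamped Euler–Maruyama Langevin dynamics,
Δx = (F_total/mγ)Δt + √(2k_BT Δt/mγ) ξ, with a 2 fs step (echoing the MD
integrator step; at these parameters Δt/τ_relax ≲ 10⁻³, so the O(Δt)
discretisation bias is far below sampling error — verified by a χ² test
of the sampled r-histogram against r²e^(−U/kT)). The inner loop is
JIT-compiled (numba) and bit-reproducible for a fixed seed; snapshots are
logged every 2 ps. A non-finite coordinate aborts with advice to reduce
the step.

What the toy model does **not** emulate: atomistic forces, internal
flexibility, solvent, or the absolute timescales of the real complex.
Passing protocol tests show the protocol logic and its phenomenology are
implemented correctly, not that the real system behaves this way.

## State detection

r(t) is smoothed with a centred moving average (default window 200 ps;
truncated at the series edges — centred alignment gives zero phase shift
and output length equals input length; both choices are ours, the
procedure's description leaves them open). Frames classify as bound
(r̄ < 2.75 nm), prebound (2.75 ≤ r̄ ≤ 3.00 nm, closed on both ends),
dissociated (r̄ > 3.20 nm by default) or transition in between; the bound
label below the band is a definition we adopt, since only the band and the
bound-state centre (2.65 nm) are prescribed. A prebound *visit* requires a
single contiguous interval of at least 1 ns ("remains … between" is read
as contiguous; the inclusive boundary reading is adopted; a cumulative-time
alternative would be laxer). Interval duration is counted as
n_frames × stride, so a planted 1.0 ns segment is exactly at threshold.
Per-state statistics use the n−1 SD normalisation with single-frame states
reported as SD 0 and count 1. Distribution overlap is the sum of bin-wise
minima of two normalised histograms on shared Freedman–Diaconis bins
(configurable).

## Interface interactions

Contacts: minimum heavy-atom distance between two selections strictly
below 0.35 nm; frequencies along r are per-bin fractions over pooled
frames, with empty bins flagged (NaN), never zero-filled. Hydrogen bonds:
the Wernet–Nilsson cone, r_DA < 3.3 Å − 0.00044 Å/deg² · δ²_HDA. Donors
are protein N/O atoms carrying a hydrogen; hydrogens are attached to the
nearest same-residue N/O within 0.13 nm (geometric typing — no
connectivity records are required); acceptors are all N/O; same-residue
pairs are excluded. Frequency tables count inter-chain bonds only and
label side-chain guanidine/ammonium donors with one "s" label per residue,
so their frequency is the frame-wise OR of the individual nitrogens. The
arginine-guanidine distance is the minimum over NE/NH1/NH2; the aromatic
centroid is the unweighted mean of the six ring carbons. SASA is
Shrake–Rupley with golden-spiral sphere points (default 960, probe
0.14 nm); per-residue areas are sums over member atoms. With equal-weight
quasi-uniform points an isolated atom's area is exact; partial burial
carries ≤ 1 % discretisation error at 960 points, and rotation invariance
holds only to that error (translation invariance is exact).

## Umbrella sampling and binless WHAM

Windows apply U_k(ξ) = ½k(ξ−ξ_k)² (GROMACS/Plumed convention — stated
because force-constant conventions differ by a factor of two across
tools) with k = 6276 kJ/(mol nm²) at the 13 centres 0.250–0.700 nm. The
window free energies solve the binless WHAM (MBAR) self-consistency
equations over the pooled samples; the solver runs 50 self-consistent
sweeps and then Newton iterations on the gauge-fixed stationarity system
to a 10⁻¹⁰ k_BT tolerance (quadratic convergence; a safeguarded fallback
to self-consistent updates handles ill-conditioned steps). Adjacent
windows with disjoint sampled ranges are an error naming the gap.

G(ξ) is evaluated on a 200-point grid spanning the window centres plus a
0.05 nm margin, from the reweighted samples with a Gaussian kernel of
bandwidth 0.005 nm (≈ 2 grid spacings). The kernel, rather than a raw
per-bin histogram, is used because the barrier readout takes a maximum
over ~10² grid values and per-bin noise biases that maximum upward
(extreme-value bias, ~0.5 kJ/mol at desk-scale sampling), while the
kernel's smoothing bias at the curvatures involved is ~0.05 kJ/mol; a
plain histogram remains available (`bandwidth=None`). Grid points with no
samples within four bandwidths are NaN. The profile is shifted to
min G = 0.

Uncertainty follows the simplified segment bootstrap: each window's
series is split in time order into five equal contiguous segments
(remainder dropped and logged), the estimator runs on every
leave-one-segment-out combination, and the per-point mean and population
SD over the five profiles are reported. For statistically independent
samples this SD understates the estimator's standard error by the
jackknife factor (m−1)/√m ≈ 1.8, because the combinations share 75 % of
their data pairwise; validation tests that compare recovered profiles
against planted truth therefore scale it accordingly, while the reported
SD keeps the scheme's plain definition. Barrier extraction locates the
minima in the bound (0.25–0.45 nm) and prebound (0.50–0.70 nm) regions —
defaults chosen because the two PMF minima of the study system sit near
0.3 and 0.6 nm — and takes the maximum of G between them relative to the
bound minimum; a profile whose inter-minima maximum sits at an endpoint is
reported as barrier-free rather than raising.

## Synthetic data

The packaged template is a programmatically built two-chain mini-complex
(40 + 30 residues): CA atoms on spherical golden spirals (radii 0.75 and
0.65 nm), backbone N/C/O/H in local tangent frames with roughly physical
bond lengths, a tyrosine ring (Tyr151, ring plane tangent to the surface
so its normal points to solvent), an arginine guanidine group (Arg17) and
an isoleucine side chain (Ile19). The geometry is schematic — no
Ramachandran realism, no force-field energetics — but non-clashing and
complete for every selection and interaction measurement the package
defines. It is a synthetic stand-in, not experimental data; the crystal
structure the study starts from is not redistributable through this
package, so the bound-pose geometry check runs against this construction
placed at r = 2.65 nm (which makes that check a round-trip consistency
test of parsing, selection and centre-of-mass code, not an independent
experimental validation).

The two-state generator places the rigid ligand so that the *drawn*
(r, Θp, Φp) are satisfied exactly (a three-point internal-coordinate
construction), then applies orientational jitter as a small random
rotation about B1 — position before orientation, because positional
shifts dominate the bound/prebound difference. The ligand's internal
orientation is stored relative to a local frame tied to the T1–B1 axis,
so at zero jitter the orientational coordinates are exactly constant
across frames. Per-state defaults echo the study system: bound
2.65 ± 0.04 nm, prebound 2.85 ± 0.05 nm, +0.2 rad shifts of Θp and Φp,
0.03 rad angular spreads and 0.02 rad jitter SD (the angular spreads and
jitter are our choices of realistic narrow distributions; only r's
moments and the 0.2 rad shifts are prescribed by the emulated system).
Planted interactions are then written into designated side-chain atoms:
an Arg17 side-chain hydrogen bond to a receptor backbone carbonyl
(r_DA = 0.29 nm, δ_HDA = 0), a heavy-atom contact (0.30 nm), and a
cation–π geometry (guanidine CZ 0.40 nm above the Tyr151 ring centroid
along the ring normal, matching the observation that this distance stays
below 0.45 nm in the intermediate). Which interaction is "on" in which
state is a plan field; the default mirrors the study system (hydrogen
bond and contact in the bound state, cation–π in the prebound state).
A clash guard errors if the rigid bodies approach within 0.12 nm.

Umbrella samples are exact iid inverse-CDF draws from the biased
Boltzmann density on a fine grid — they validate the estimator, not MD
autocorrelation handling. Dwell series are piecewise Ornstein–Uhlenbeck
(τ = 20 ps) around each segment's level, initialised at the level on
segment entry so a zero-noise plan reproduces the planned step function
exactly; ground-truth intervals are returned alongside.

## Problem sizes and determinism

Validation runs use 10–20 seeded runs per protocol scenario, 150–300
frames per state for trajectory round trips, 4000 samples per umbrella
window, and 5–10 ns of unbiased sampling for the equilibrium check —
sizes at which every assertion's statistical tolerance (3 SE bands, χ²
p > 0.01, 3× bootstrap SD) holds with margin while the whole suite stays
interactive. All randomness flows through NumPy PCG64 generators (the
Langevin kernel uses numba's Mersenne–Twister, seeded per run); fixed
seeds give bit-identical outputs, and the pipeline emits a manifest
(config hash, seeds, versions, timings) so a run can be reproduced
exactly.

## Known limitations

The reduced dissociation model is radial: it cannot show the positional
(Θp, Φp) signature of the intermediate, only the r-signature; positional
shifts are exercised through the rigid-body generator instead. Hydrogen
typing is geometric, so exotic protonation states are not inferred.
Contact/H-bond scans are all-pairs per frame (fine for interface-sized
selections; no neighbour lists). The WHAM uncertainty is the scheme's
plain 5-combination SD, which is known to be conservative in neither
direction for correlated MD data — for serious error bars on real
trajectories, block-length sensitivity should be checked. mmCIF,
solvent boxes, velocities and bond-order perception are out of scope.
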