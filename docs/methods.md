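# Methods

This note documents the models and procedures implemented in `bklinker`,
the parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish about real data.

## Trajectory model

Coordinates are held in memory as frames × atoms × 3 arrays in Å with
per-frame orthorhombic box lengths and times in ns. Residue numbering is
taken verbatim from the input files (hSlo1 author numbering, so the
C-linker is R329–K343). Reading goes through MDAnalysis (PDB/PSF topology,
DCD/XTC coordinates); a PDB alone yields a single-frame trajectory.
Triclinic boxes are rejected explicitly rather than silently mishandled —
only orthorhombic minimum-image arithmetic is implemented, which covers
membrane-protein production boxes.

Superposition uses the standard SVD (Kabsch) least-squares solution with
reflection correction; the default fit selection is protein Cα and the
default reference is frame 0. Selections of fewer than three atoms, or
collinear ones, are rejected because the rotation is then underdetermined.
RMSF assumes a pre-superposed trajectory and picks one representative atom
per residue (Cα); residues without a matching atom are returned in a
skipped-residue list, never silently dropped. Analyses that conventionally
use an equilibrated tail of the trajectory take an explicit frame window;
`Trajectory.last_window(150.0)` reproduces the common "final 150 ns"
convention and warns (and uses everything) when the trajectory is shorter.

## Dynamic-network coupling

Each residue is a node at its Cα. The normalized fluctuation correlation

    C_ij = <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>),  Δr_i(t) = r_i(t) − <r_i>

is computed from 3-D displacement vectors over a strided frame sample; a
zero-variance node is an error (the normalization is undefined), naming the
residue. Edges require the minimal heavy-atom pair distance ≤ 4.5 Å in at
least 75 % of the same sampled frames; surviving edges carry weight
w_ij = −log|C_ij| (natural log — the path *ranking* is invariant to the
base, so the minimal assumption is used; total lengths scale by the
base-change constant). Edges with C_ij = 0 would have infinite weight and
are removed. Sequence-adjacent residues are eligible edges by default,
because the object of interest is a covalent linker pathway; an exclusion
flag reproduces conventions that drop them.

The optimal path is the minimum-total-weight simple path. Ties are broken
deterministically by the lexicographically smallest node sequence — a small
Dijkstra variant implements this, because library routines do not expose a
deterministic tie-break; networkx Floyd–Warshall and Dijkstra all-pairs
distances are both exposed so their agreement is testable, and Yen's
loopless k-shortest-path enumeration (networkx `shortest_simple_paths`)
produces the optimal + k suboptimal paths, re-sorted with the same
tie-break. "Top-k" enumeration, rather than a length-tolerance band, was
chosen because it is deterministic and matches how suboptimal-path sets are
usually reported. `path_domain_fraction` summarizes how many ranked paths
cross a residue set (a linker, a neighboring chain).

## Membrane-anchoring metrics

All distance criteria are inclusive at the cutoff ("no greater than"):
C–C hydrophobic contact 4.5 Å; π-cation 5.0 Å from the mass-weighted
centroid of the six ring carbons (equal-weight in practice, stated for
determinism) to a choline N; contact maps 5.0 Å over residue heavy atoms.
Hydrogen bonds use D–A ≤ 3.0 Å and D–H–A ≥ 150°; these widely used
geometric defaults are explicit and configurable because "default criteria"
of analysis tools differ. Donor hydrogens are resolved geometrically
(same residue, ≤ 1.25 Å in frame 0) since PDB topologies carry no bond
table. The default lipid acceptor set is the headgroup N plus all headgroup
oxygens; it is a selection argument, so narrower conventions (phosphate O
only) are one line away.

SASA burial is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points — agrees with a 10× finer grid to well under 2 % on
ring-plus-tail geometries), probe 1.4 Å and Bondi-type radii. Burial is
SASA(sidechain | protein context) − SASA(sidechain | context + lipid
tails), clipped at zero; an isolated atom scores exactly 4π(r+probe)²
because all quadrature points are accessible.

Pore hydration is counted in an explicitly parameterized cylinder (default
radius 10 Å) between two residue-ring planes (mean Cα z of each ring); this
parameterization is a documented stand-in for hydration criteria defined
elsewhere, and outputs should be read as such.

Replica aggregation time-averages each replica over the analysis window
first, then reports mean and SEM = sd/√n **across replicas** (never across
correlated frames). A single replica yields SEM = NaN with a warning,
never a fabricated value.

## Electrophysiology

Relative conductance comes from macroscopic tail currents at a fixed
repolarization voltage: amplitude per sweep = mean current over the tail
window minus a baseline mean (default: pre-pulse samples), so any constant
offset cancels. The Boltzmann relation is fitted by nonlinear least squares
(lmfit) with the amplitude (G_max or Q_max) as a free parameter when
normalizing — more robust to noise at extreme voltages than dividing by the
observed maximum, and it makes V₀.₅ and b exactly invariant to rescaling
the raw amplitudes. Initialization: V₀.₅ from the linear-interpolated
half-max crossing, b = 15 mV. The default temperature is 296 K
(room-temperature recordings); z = kT/(e₀·b) so z·b ≡ kT/e₀ at fixed T.
Fits of averaged curves are the default route; per-patch fitting followed
by averaging is available by fitting each column of a replicate-layout CSV.

## Horrigan–Aldrich model

The dual-allosteric tetramer model:

    Po = L(1+KC+JD+JKCDE)^4 / [L(1+KC+JD+JKCDE)^4 + (1+K+J+JKE)^4]
    L = L0·exp(+ZL·V/kT),  J = exp(+ZJ·(V−VH)/kT),  K = [Ca]/KD

Sign convention: depolarization increases both L and J (printed forms of
the exponentials circulate with inconsistent signs; the convention above is
the one that yields physiological behavior and reproduces the published
wild-type fits — with L0 = 3.5e-07, ZL = 0.18, ZJ = 0.59, VH = 159 mV,
C = 10, D = 48, E = 4.2, KD = 18 µM it gives V₀.₅(0 Ca) ≈ 180 mV).
Default T = 298.15 K, kT/e₀ = 25.693 mV, configurable. Both partition
terms are evaluated in the log domain (logsumexp over term logs), stable
far beyond V ∈ [−300, 400] mV. V₀.₅ solves equality of the two terms by
Brent root-finding on the log-difference in a default bracket of
[−400, 500] mV (wider brackets are a parameter; weak-coupling sweeps need
them). An independent 0.01 mV grid sign-scan of the same residual is
provided as a slow cross-check of the solver. In the decoupled limit
C = D = E = 1 the midpoint satisfies L(V₀.₅) = 1, i.e.
V₀.₅ = −kT·ln(L0)/ZL, which the solver reproduces exactly. Sensitivity
sweeps vary only D or L0 with all other parameters fixed and report V₀.₅
against the inverse parameter at each Ca.

## Synthetic data: what it emulates, and what it does not

*Planted-correlation trajectories* place one bead per residue on straight
chains (3.8 Å spacing, chains separated beyond the contact cutoff) and add
a shared latent Gaussian series per residue block along z plus isotropic
private noise. The private-noise parameter is the **total 3-D** sd, so the
same-block correlation is exactly
a_i a_j σ_s² / √((a_i²σ_s²+σ_i²)(a_j²σ_s²+σ_j²)) and cross-block
correlation is exactly 0. Defaults (latent sd 0.5 Å, noise 0.3 Å) keep
contact persistence safely above the 75 % threshold so the planted
adjacency is recoverable exactly. Displacements are i.i.d. per frame — no
autocorrelation — which is the simplest model with a closed-form C_ij;
empirical estimates therefore converge at the 1/√N rate, and at 10⁴ frames
nonzero entries are recovered within ±0.02 while null entries show pure
sampling noise within ±0.05.

*Toy membranes* are square pseudo-POPC lattices (P at the interface plane,
choline N 1.5 Å above, tail carbons every 3 Å below; POPC atom names so
real-system selections run unchanged) around an ideal Tyr sidechain at a
controlled depth, with optional Gaussian jitter and zero-jitter ground-truth
counts computed from the as-built geometry.

*Synthetic electrophysiology* produces sweep families whose tail plateau is
Gmax·Po(V)·0.8 with per-sample Gaussian noise (no deactivation kinetics, so
window means equal amplitudes exactly), and G-V tables drawn from the
Horrigan–Aldrich model with the exact midpoint attached.

Passing tests on these fixtures establishes the *statistical and geometric
correctness* of each analysis: estimator convergence, cutoff inclusivity,
path optimality, fit recovery. They do not establish force-field realism,
lipid heterogeneity, sampling convergence of multi-µs trajectories, or
channel kinetics — published MD-derived averages (per-construct anchoring
counts, ~30 Å linker extension, sub-Å state RMSDs) require the original
trajectories and are covered here only by construction-matched fixtures
and property suites. For the same reason the published G-V source tables
are represented by synthetic stand-ins generated from the published
Boltzmann parameters (V₀.₅ per construct; G-V slope 18 mV — a
representative BK value, since G-V slopes are not tabulated — and the
printed Q-V slopes), with 2 % amplitude noise over 15 voltages spanning
V₀.₅ ± 3b.

## Problem sizes and determinism

Default analysis scales are set for interactive use: 10⁴-frame planted
fixtures, 200-graph path-oracle batteries, 200-curve fit-recovery batteries,
960-point SASA quadrature. Every stochastic component takes a NumPy seed
(`default_rng`), generators are bit-reproducible under a fixed seed, and
path tie-breaks, selection resolution and CSV layouts are deterministic, so
re-running a pipeline from its emitted effective-config file reproduces
outputs byte-identically.

## Known limitations

- Correlation uses Cα beads only (no side-chain or mass-weighted variants).
- Contact persistence and correlation share one frame sample; analyses
  needing different sampling for the two must call the stages separately.
- The H-bond donor-hydrogen resolution is geometric; exotic protonation
  states need explicit donor selections.
- The pore-water cylinder is a stand-in parameterization (see above).
- No fitting of Horrigan–Aldrich parameters to experimental G-V families;
  the model is used in simulation mode with published parameter sets.
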