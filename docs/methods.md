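# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `polysia`.  Units are fixed package-wide:
kJ/mol, nm, degrees, K; k_B = 0.008314463 kJ mol⁻¹ K⁻¹.  Angles live on
[−180°, 180°) and are re-wrapped after every arithmetic operation.

## Synthetic model surfaces and the Metropolis surrogate

The package replaces solvated MD with a seeded Metropolis chain on
closed-form torsional potentials.  This is a deliberate trade: the
sampler's stationary distribution is exactly the Boltzmann weight of a
surface whose partition function is computable by 1° grid quadrature,
so every downstream stage (bias build-up, reweighting, map
construction, TI/OSP) can be validated against an independent exact
reference.  What the toy does *not* emulate: solvent friction and
dielectric screening, ring-puckering/torsion coupling, bond and angle
fluctuations, or any force-field energetics.  Passing tests therefore
demonstrate the correctness of the *analysis machinery*, not the
physical accuracy of any particular sialic-acid ensemble.

The dimer-like presets place three Gaussian (ϕ,ψ) wells (width 25°) at
A = (60°, 120°), B = (−60°, −120°), C = (160°, −60°); well depths are
chosen so the relative free energies at 300 K are ≈ (0, 23.3, 13.67)
kJ/mol for the `dimer1_like` surface and ≈ (6.6, 12.1, 0) kJ/mol for
`dimer2_like`, whose A-well is also shifted to ϕ = 30°.  ω7 sits in a
single Gaussian well at +60° (depth 20 kJ/mol, width 20°), tight enough
that the g+ rotamer dominates and ³J(H6,H7) stays below 1.5 Hz; ω8 has
two wells at 60° and 180° (depths 12/8 kJ/mol for dimer1-like, 8/12 for
dimer2-like, width 30°), making the anti rotamer dominant in the
dimer2-like surface.  Only the well *positions* and the three relative
(ϕ,ψ) free energies follow published observations; barrier heights and
widths are package choices and are not claimed to equal any force-field
surface.  The `double_well_1d` preset,
U = B(1−cos 2(x−m₁))/2 + δ(1−cos(x−m₁))/2 with defaults B = 25, δ = 3
kJ/mol, m₁ = 60°, is the 1D workhorse for sampler and LEUS validation.

The Metropolis move is a uniform perturbation of one torsion per step
(±step_size, default 30°), torsions chosen cyclically — simple, ergodic
and deterministic given the seed.  Seeds are explicit function
arguments everywhere; the inner loops are compiled with numba for
throughput (about 10⁶ steps/s for 1D systems on one core).

## Local elevation umbrella sampling

Bias grids follow the canonical parameterization: N_g = 36 bins per
torsion, deposit width σ = 360°/N_g, increment c = 0.005 kJ/mol.  Bin k
is the half-open interval centered at −180° + 360°(k+½)/N_g.  Two
choices the protocol leaves open are resolved as follows and exposed as
parameters:

* **Bias functional form** — each deposit adds a periodic Gaussian of
  width σ centered at the occupied bin's center (product kernel in 2D);
  continuous and differentiable, the standard local-elevation choice.
* **Deposition frequency** — one increment of c at the currently
  occupied bin every `deposition_stride` MC steps (default 1).

Bias evaluation truncates Gaussian tails beyond 4σ (measured in bins
from the current position); the truncation error per deposit is below
e⁻⁸ ≈ 3×10⁻⁴ of c, and because the recorded per-frame bias energy uses
the same truncated rule as the sampling kernel, reweighting remains
exactly self-consistent.  Reweighting weights are computed as
exp(U−U_max) (max-shift) since built biases reach tens of k_BT.
Statistical errors come from block averaging over 10 contiguous blocks;
occurrence errors use a binomial estimate on the weight-effective
sample size (Σw)²/Σw².

A 4D build over (ϕ, ψ, ω8, ω7) is intentionally unsupported; the
two-2D-grid factorization is the efficient configuration and
`us_sample` accepts any number of frozen grids, summing their energies.

Free-energy maps assign G = −k_BT ln P per bin from the reweighted
histogram, shift the visited minimum to zero and mask never-visited
bins (no number is invented for them; plots render them dark, contours
at 5 kJ/mol).  Map interpolation (`value_at`) is periodic (bi)linear;
masked bins enter at max-visited-G + 25 kJ/mol so that ranking against
them is possible without NaN propagation.

Test problem sizes: the 1D LEUS end-to-end check uses a 5×10⁵-step
build and 10⁶-step umbrella run; the 2D check uses 2×10⁶ and 5×10⁶
steps on a three-well surface.  At these lengths the per-bin
statistical error of G is ≈ 0.05–0.15 kJ/mol, so the 0.5 kJ/mol
acceptance band on the maximum bin deviation is dominated by a safety
margin rather than noise.

## J couplings

³J(H6,H7) and ³J(H7,H8) use the Haasnoot relation with
P₁–P₇ = (13.7, −0.73, 0, 0.56, −2.47, 16.9, 0.14) and Huggins
electronegativity differences relative to H (O 1.3, N 0.85, C 0.4),
shipped as a named default set and overridable.  The β-substituent
correction is applied subtractively, Δχᵢ = Δχ_α − P₇ ΣΔχ_β, the form of
the original seven-parameter calibration; with the shipped Δχ table it
reproduces the expected rotamer extremes of the sialic H7–C7–C8–H8
fragment (gauche < 2 Hz, anti > 9 Hz, the anti value matching the
≈9.5 Hz measured for the free glycerol arm), whereas an additive
correction would cap the anti coupling near 8 Hz.

Orientation signs pair the two substituents on each carbon with
opposite parity (O7 −, C6 + on C7; O8 −, C9 + on C8), as the Newman
geometry requires; the assignment is part of the shipped pattern and
configurable per fragment.  When couplings are computed from a torsion
trajectory, the proton–proton torsion is derived from the heavy-atom
torsion by tetrahedral offsets; with protons placed at ±120° on either
carbon the two offsets cancel, so the default θ-offset is 0°,
configurable per coupling for other stereochemistries.  On Cartesian
ensembles θ is measured directly from the (explicit or virtual) proton
positions.  ³J(H8,H9R/S) evaluates the DFT-parameterized cosine/sine
series in ω9, with the S relation shifted by −120°.  Ensemble couplings
are linear averages of per-frame J, reweighted when LEUS weights are
supplied.

## Virtual protons, NOE averaging, hydrogen bonds

United-atom carbons get protons by ideal construction at 0.1 nm: CH
opposes the mean of its three heavy-neighbor directions; prochiral CH₂
takes both tetrahedral completion positions (R/S assigned by the
handedness of the neighbor/proton triple, so mirror images swap labels)
plus their midpoint site; CH₃ collapses to a pseudo-site on the carbon.
Upper-bound corrections: 0 (CH), 0.09 nm (CH₂ midpoint), 0.1 nm (CH₃).
The exact geometric constants of force-field virtual sites are not
reproduced — ideal tetrahedral geometry is used and documented.

NOE effective distances are ⟨r⁻⁶⟩⁻¹ᐟ⁶ with optional weights.  Hydrogen
bonds use the geometric criterion H···A < 0.25 nm and D–H···A > 135°;
donors are O–H/N–H with explicit protons, acceptors all oxygens, with
the chemically equivalent carboxylate pair pooled as "O1A/B".  Reports
filter at 2% occurrence by default.

## Fragment builder

Residues are built on an exact closed six-ring (C2–C3–C4–C5–C6–O6) in
an alternating-displacement chair solved for uniform ring bonds of
0.150 nm and tetrahedral vertex angles, with substituents on ideal
internal coordinates (C–C 0.153, C–O 0.143, O–H 0.100, C–H 0.109 nm).
The N-acetyl group is simplified to N5(–H)(–CH₃) with torsions chosen
to clear the ring substituents for any side-chain rotamer.  Side-chain
torsions ω7/ω8/ω9 are set exactly by natural-extension (NeRF)
placement.  Chains grow from the reducing end (residue 1 = label "a"):
the next residue's anomeric carbon is placed from ψ, its ring oxygen
from ϕ, and the residue template is grafted by an exact three-point
rigid superposition, so requested glycosidic torsions are reproduced to
machine precision (the contract is 1°).  Anomeric configuration swaps
the axial/equatorial assignment of the C2 substituents.  Steric clashes
(non-bonded pairs < 0.08 nm, 1–2 and 1–3 exempt) are flagged on the
ensemble, never fatal — the decamer enumeration uses the flags to
select non-clashing candidates.

## Restraints and free energies

NOE-derived distance restraints default to attractive-half-harmonic
(penalizing only violations above the bound), matching upper-bound
semantics; hydrogen-bond distance restraints and dihedral restraints
are full harmonic; both styles are switchable per restraint since the
original protocol is ambiguous on this point.  Dihedral deviations use
the minimal-image difference in (−180°, 180°].

The soft bond is implemented with the softness factor dividing the
force constant,

U(r,λ) = ½[(1−λ)k_A/S_A(r,λ) + λk_B/S_B(r,1−λ)]·(r − ((1−λ)r₀A + λr₀B))²,
S_X(r,λ) = 1 + αλ(r−r₀X)²,

which keeps ∂U/∂λ bounded by ≈ k_B/α when a restraint is switched on
from k_A = 0 — the purpose of the construction; a multiplicative
softness would instead grow as r⁴.  ∂U/∂λ is analytic and verified
against central finite differences.

TI uses a 12-point λ schedule densified near the endpoints
(0, 0.025, 0.05, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.95, 1), chains
warmed sequentially (each λ starts from the previous endpoint),
trapezoid quadrature, and per-λ block errors combined through the
trapezoid weights.  The endpoint placement is a package default; the
doubling-density test guards against discretization sensitivity.  OSP
computes −k_BT ln⟨e^{+U_res/k_BT}⟩ by log-sum-exp and warns when
max|U_res|/k_BT exceeds 10 (poor overlap).  The toy free-energy cycle
(double-well torsion, λ-coupled dihedral restraint on, OSP release)
closes against the identity reference, with the TI leg checked against
quadrature.  The headline restraint free energies of solvated
tetrasialic acid are *not* reproducible with these toys and are out of
scope by design; the cycle arithmetic (e.g. composing a TI leg with an
OSP leg) is what the package verifies.

## Clustering, puckering, enumeration

Daura-style clustering takes the frame with the most RMSD-neighbors
within the cutoff (ties to the lowest index, making the partition
deterministic), removes the cluster and recurses; RMSD is computed
after quaternion least-squares superposition on all heavy atoms by
default (selection configurable).  Cremer–Pople coordinates follow the
generalized puckering construction (mean-plane normal from the
sin/cos-weighted position sums); the package reports Q (nm),
θ = atan2(q₂, q₃) ∈ [0°, 180°] and φ₂ ∈ [0°, 360°).  Idealized
reference values for named conformers are not tabulated; analytic
templates (planar, alternating chair, pure-m=2 equator) are the tested
anchors.  Decamer enumeration forms the Cartesian product of per-linkage
candidate states over the four pentamer linkages, repeats the pattern
periodically over all nine linkages, builds each candidate to flag
clashes, and ranks by the summed interpolated map free energy of its
linkage settings.

## Pipelines

`run_leus_pipeline` builds both 2D biases, umbrella-samples with the
frozen pair, and emits map CSV/PNG, a J-coupling table (merged against
an experimental CSV with columns residue/coupling/value/uncertainty
when supplied) and a hydrogen-bond report computed on 3D dimer frames
rebuilt from the sampled torsions.  `run_restrained_pipeline` samples
an oligomer's linkage and side torsions by Metropolis with the energy
evaluated on the rebuilt Cartesian frame (model torsional terms +
restraint energies) and reports violations, clusters and puckering;
the built-in default restraint set for the tetramer mirrors the
3-H-bond + 2-dihedral protocol.  `run_freeenergy_pipeline` runs the
TI/OSP cycle on the double-well toy.  Every pipeline writes a
provenance record (canonical config hash, seeds, versions) and no
timestamps, so reruns are byte-identical.  ³J(H8,H9R/S) appears in
pipeline J tables only when ω9 is among the sampled torsions; the
4-torsion presets deliberately stop at (ϕ, ψ, ω7, ω8), the degrees of
freedom the enhanced sampling targets.

Default pipeline problem sizes (2×10⁵ LE + 4×10⁵ US steps, a few
thousand restrained-sampler steps, 4×10⁴ production steps per λ) are
chosen so a full workflow completes in seconds to minutes on one core
while keeping per-quantity statistical errors at the few-percent level
reported alongside every average.

## Known limitations

* The torsional toys carry no excluded volume beyond clash *flagging*;
  restrained sampling can visit conformations a force field would
  forbid.
* Virtual-proton geometry is ideal-tetrahedral, not force-field
  calibrated; absolute NOE distances on built fragments inherit this.
* The fragment builder's ring is rigid (no puckering dynamics), so
  puckering analyses on built ensembles test machinery, not ring
  thermodynamics.
* `LambdaSystem1D` covers one-dimensional λ-coupled Hamiltonians; TI on
  multidimensional toys would need a dedicated system class.
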