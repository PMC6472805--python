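# Methods

`ecmdyn` models how contractile cells plastically remodel fibrous
extracellular matrices (collagen I, fibrin) on two scales: a discrete
crosslinked fiber network driven by dynamic, filopodium-like point forces,
and a spherically symmetric viscoplastic continuum with elastic damage and
plastic softening. A third module implements the quantification metrics
used on 3D displacement and intensity measurements, with a synthetic
fixture generator so the metric chain is testable without imaging data.

Units throughout: pN, μm, s (so pN/μm² ≡ Pa); thermal energy k_B·T at
310 K is 4.28×10⁻³ pN·μm.

## Discrete fiber network

### Model

Fibers are chains of cylindrical segments with harmonic stretching
(U_s = ½κ_e Δr² per segment, Δr the deviation from the rest length) and
harmonic bending (U_b = ½κ_b Δθ² per interior node, Δθ the deviation of
consecutive segment directions from straight). Non-adjacent segment pairs
closer than one fiber diameter repel through a quadratic overlap penalty
capped at a configurable force, standing in for volume exclusion.
Crosslinks are two-armed springs attached at fixed arc coordinates on two
segments of distinct fibers; their nodal force distribution uses
lever-arm weights, which reproduces the point force and its torque
exactly. A crosslink forms unstressed: its rest length is the
closest-approach distance of the two segments at formation (capped at
the full two-arm reach), the same zero-strain rule used when an unbound
crosslink rebinds. Crosslinked pairs are excluded from volume exclusion,
as bonded pairs are in molecular force fields: the crosslinker occupies
the contact, and letting the overlap penalty fight the crosslink spring
would lock permanent frustrated prestress into the network.

The network is athermal and overdamped: every free node obeys
ζ·dr/dt = F(r), integrated with forward Euler. The box is periodic in x
and y; fiber ends near the +z face are pinned (far-field resistance) and
z = 0 — the cell side — is a rigid wall.

Crosslinks are slip bonds: each bound crosslink unbinds per step with
probability 1 − exp(−k_u·Δt), where k_u = k_u0·exp(λF/k_BT) and F is the
current tensile (never compressive) spring force. Optionally an unbound
crosslink whose attachment loci drift back within a capture distance
rebinds at a constant rate; it reattaches at the current separation with
zero strain, so rebinding can never inject elastic energy.

Loading mimics cycling filopodia: during the loading phase every segment
whose midpoint lies within 2 μm of the z = 0 boundary receives a point
force of fixed magnitude toward that boundary; segments entering the zone
acquire the force, segments leaving lose it. (A per-fiber variant —
one force per fiber with any segment in the zone — is available behind a
flag.) After a fixed load duration all external forces vanish, mimicking
decellularization, and the network relaxes toward a new, possibly
plastically remodeled, state. Times are reported on the normalized axis:
0 = load onset, 1 = load cessation, relaxation extending beyond 2.

### Parameters

Measured or literature-anchored values: fiber diameter 0.1 μm, fiber
material modulus 125 MPa (from which κ_e = EA/ℓ₀ and κ_b = EI/ℓ₀ derive
unless overridden), crosslink arm 20 nm, loading zone 2 μm, full domain
20×20×20 μm³, loading forces 1 pN–1 nN.

Assumed values (no published baseline; all exposed in `SimConfig` and
flagged at load time): nodal drag ζ = 1 pN·s/μm; zero-force unbinding rate
k_u0 and mechanosensitivity λ "1x" baselines; crosslink spring stiffness
(fibers are far stiffer than the crosslinker molecule, so the default is a
soft 300 pN/μm); repulsion stiffness 500 pN/μm; segment rest length
0.5 μm; mean fiber length 8 μm; fiber count from a line density typical of
a few-mg/mL gel. Since only normalized time is reported, the physically
meaningful kinetic quantities are the dimensionless groups k_u0·T_load
(fraction of unloaded bonds lost per loading phase) and λF/k_BT (force
amplification of unbinding), and the defaults are set through them.

### Desk-scale study conditions

All shipped tests and the acceptance script use `desk_config()`: a
10×10×10 μm³ box with 500 fibers of 6 μm (1 μm segments) and a 75 nm
crosslinker arm, giving ≈5 crosslinks per fiber at the 1x density and a
fully percolating network. Fibers are softened to E = 0.32 MPa
(κ_e ≈ 2.5 nN/μm) with κ_b = 10 pN·μm and stiff crosslink springs
(2 nN/μm), so that an explicit time step of 6×10⁻⁵ s resolves both the
stiffest springs and micrometers of fiber transport within a 0.25 s
loading phase, while a fully bound network barely yields elastically
under the zone forces. The kinetic baselines (k_u0 = 0.05 s⁻¹,
λ = 0.3 nm at 1x) put the two dimensionless groups in the regime of
interest: an unloaded crosslink passes the loading phase safely
(k_u0·T_load ≈ 0.013) while one carrying ~100 pN unbinds within it
(λF/k_BT ≈ 7). These conditions were fixed once, before the behavioral
tests were frozen, and are the package's definition of its study
conditions.

One desk-scale artifact matters for how the connectivity trends are read
out. At the full-scale fiber modulus (125 MPa) an intact, fully
crosslinked network is effectively rigid against piconewton-scale zone
forces, so its transient accumulation stays near 1; at the desk modulus
the same network sags visibly during loading and recoils on unload.
The plasticity-sensitive trends — the biphasic dependence of recruitment
on crosslink density and on bond mechanosensitivity — are therefore
asserted on the persistent (post-relaxation) accumulation, where the
elastic excursion has recovered, rather than on the peak. The
force-response (sigmoid) and stress-retention trends are peak-based as
usual.

What the desk scale preserves: percolating connectivity, force-graded
slip-bond kinetics, transport into and out of the loading zone, mass
conservation, plastic vs elastic recovery. What it does not: absolute
stress magnitudes and absolute times (both are reported in model units on
the normalized time axis), the factor-of-hundreds scale separation of a
real gel's fiber modulus, and the full 20 μm domain of the full-scale
configuration (available but too slow for routine testing).

### Numerics

Forces are exact gradients of the potentials (verified against central
finite differences at 10⁻⁴ relative tolerance) and are computed by a
numba-compiled fused kernel; a pure-numpy reference implementation of
every term is kept and the two are asserted equal in the tests. Neighbor
lists for repulsion come from a cell-list shortlist (midpoint cutoff =
segment length + diameter + skin) rebuilt every 15 steps with a 0.2 μm
skin. The Euler step enforces a stability cap on the per-step
displacement (default ℓ₀/10) and raises rather than integrate an unstable
trajectory. One RNG stream drives the kinetics; one uniform draw per
crosslink per step is consumed in index order regardless of bound state,
so event sequences are reproducible and comparable across model variants
at a fixed seed.

Prestress relaxation integrates the unloaded, kinetics-frozen dynamics
until the total elastic energy plateaus (relative change < 10⁻³ per
100-step window) and the largest free-node force drops below 1 pN.
Unbinding is disabled during this phase so the reference state is a
prestress-free, fully crosslinked network.

Concentration profiles spread each segment's rest length (its monomer
mass) uniformly over its current z-extent, clipped to 1 μm bins and
normalized by the uniform initial density — mass is conserved exactly, so
the length-weighted profile mean is 1 at every snapshot by construction
and the tests assert drift < 0.1 %. Cross-plane stress sums the
z-projected axial tensions of segments and bound crosslinks crossing the
mid-domain plane, divided by the plane area; bending shear is excluded
(axial tension only).

## Continuum model

### Model

A cell of radius a = 10 μm (assumed; used only to express distances in
cell diameters) sits in a spherical shell of matrix, a ≤ r ≤ R = 10a,
outer boundary fixed. The cell pulls the matrix inward with a radial
traction p at r = a, ramped up over 60 s, held during a creep phase,
ramped down, and followed by a zero-load settle — the continuum analogue
of contraction and decellularization.

The material is elastic-viscoplastic. Elasticity is linear and isotropic
with Young's modulus degraded exponentially, E = A·e^(−Bε₁), by the
running maximum tensile principal elastic strain ε₁; A and B are fixed by
the anchors (ε_1s = 0.02, E_s = 1 kPa) and (ε_1e = 0.06, E_e = 0.2 kPa),
with E = E_s below onset and E = E_e beyond saturation. Tracking the
running maximum makes damage irreversible, standing in for force-driven
crosslink loss. Plastic flow follows a Norton-Hoff overstress power law
with von Mises direction, dε_p/dt = k·⟨(σ_vm − σ_y)/σ_ref⟩ⁿ, and the
yield stress softens linearly with accumulated equivalent plastic strain
beyond a critical value, floored at a positive minimum ("plastic
damage").

### Parameters

Measured/stated values: E_s = 1 kPa, E_e = 0.2 kPa, ε_1s = 0.02,
ε_1e = 0.06, p = 0.1 kPa, creep durations 300 s / 1500 s / 1 h.

Assumed values (flagged at config load): ν = 0.3; σ_y0 = σ_ref = 45 Pa;
softening slope −300 Pa per unit plastic strain beyond ε_p,crit = 0.02,
floored at 25 Pa; Norton-Hoff coefficient 10⁻⁴ s⁻¹ with exponent 2. They
were calibrated — once, as the package's study conditions — so that the
p = 0.1 kPa baseline yields within the creep window, the interface
displacement is a few μm (the experimental scale), plasticity is a
moderate fraction of the deformation, and softening visibly lowers the
recoverability index relative to the no-softening variant (≈76 % vs
≈82 % at 1500 s creep). Under these conditions the headline outputs
emerge from the model rather than being imposed: the far-field elastic
decay exponent is −2.00, the half-max damage radius is ~0.6 cell
diameters at 1500 s growing toward ~1 diameter at 1 h (well inside the
3-diameter bound), and the peak back-calculation error approaches the
modulus-degradation factor E_s/E_e = 5.

### Back-calculated ("apparent") stress

Two apparent stresses are formed from the model's own displacement
fields, both evaluated with the pristine modulus E_s and no plasticity:
one from the total deformation at the end of creep, and one from the
deformation recovered on unload — the traction-force-microscopy protocol.
The comparison uses the radial stress component, the normal stress a
traction reconstruction reports. This choice makes the damage-only limit
exact: with identical strain fields the pointwise ratio reduces to
E_s/E(r) ≤ E_s/E_e, and plasticity perturbs it only through residual
strains. A von Mises version of the same ratio additionally folds the
deviatoric plastic relaxation of the true stress into the "error" and is
therefore not used for the headline number.

### Numerics

Quasi-static radial equilibrium, dσ_rr/dr + 2(σ_rr − σ_θθ)/r = 0, is
discretized with linear finite elements on a 160-point geometric grid
(one-point quadrature, element-midpoint state) and solved as a tridiagonal
system each step, with the plastic strain entering as an eigenstrain
load. Within a time step, equilibrium and the damage modulus are iterated
to a fixed point; because the driving strain is a running maximum the
iteration is monotone and always converges. Plastic flow is advanced
explicitly with the time step adapted so the equivalent plastic increment
never exceeds 1.5×10⁻³ per step. Halving the grid spacing and the plastic
step changes the recoverability index and the damage radius by less than
1 % (asserted in the tests). The pure-elastic mode reproduces the
pressurized-cavity closed form u(r) = −p a³/(4G r²) to 0.5 % and recovers
completely on unload; the elastic-decay preset pushes the outer boundary
to 50a so the fixed boundary does not bias the log-log slope over the fit
window (2a–5a).

The spherical reduction sacrifices the local contact detail of an annular,
slightly off-edge load; outputs tied to that geometry (e.g. local
compressive states at the cell surface) are outside this model's reach,
and the "load application region" is simply the cell-ECM interface.

## Remodeling metrics

Displacement length is the mean displacement magnitude over a cubic ROI
(default 60 μm side). The densification factor is the ratio of the
radial intensity line integral over the first 5 μm outward from the cell
membrane (membrane located by interpolating the mask isosurface along
each ray) to a matching 5 μm integral starting 25 μm from the membrane,
each averaged over sampling rays — four axis-aligned rays through the
mask centroid by default, configurable. The recoverability index is
100·‖u_decell‖/‖u_overall‖; values above 100 % are reported with a
warning, not clipped. Radial decay profiles sample |u| along rays from
the membrane and normalize by the membrane value.

The synthetic fixture generates a radially contracting field
u(r) = −u₀(a/r)ⁿ r̂ outside the cell (linear ramp inside), splits it into
an elastic fraction f (the decellularization field) and a plastic
remainder — so the per-voxel identity plastic = overall − decell holds
exactly — and builds an intensity volume with a densified shell at a
stated ratio within 5 μm of the membrane. The shell is padded by ~1.5
voxels on each side of the measurement window so that the stated ratio is
the plateau level a line integral sees; without the padding, trilinear
sampling clips the shell edges and deterministically underestimates the
ratio. Optional Gaussian noise is added per voxel and component.

For exponent recovery under noise, `fit_decay_exponent` removes the known
measurement noise floor before fitting (E|u|² ≈ u² + 3σ²); with 5 % of u₀
per-component noise this recovers the exponent to better than 2 % where a
naive log-log fit of |u| is biased shallow by ~5 %. With that correction,
random (n, f, densification ratio) are recovered within 3 % across 20
seeded fixtures — on these idealized radially symmetric fields. Real DVC
data add correlated noise, anisotropic cells and heterogeneous gels, which
the fixture does not emulate; passing these tests shows the metric chain
is implemented correctly, not that it is robust to those effects.

## Known limitations

* The discrete engine's absolute stresses and times are meaningful only
  relative to its own unit choices; comparisons to experiment are through
  normalized time and normalized concentration.
* Explicit Euler plus hard z-clamping means very large loads need a
  smaller time step; the integrator refuses (with a clear error) rather
  than silently losing accuracy.
* No fiber rupture, intra-fiber sliding, branching, thermal fluctuation,
  polymerization during loading, or multiple crosslink species.
* The continuum model is 1D spherically symmetric; anisotropic loading,
  discrete filopodial contact patches, and non-radial fields are out of
  scope. Its constitutive constants beyond the stated anchors are
  assumptions, and its outputs should be read as regime-level, not
  fitted, predictions.
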