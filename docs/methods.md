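# Methods

`cgsaxs` infers the domain conformations a multi-domain protein adopts in
solution by combining three ingredients: (1) coarse-grained structure-based
Langevin sampling of domain arrangements, (2) per-snapshot SAXS profiles
computed with the Debye formula, and (3) cut-off screening of snapshots
against a target scattering curve by the double criterion chi2 < chi2_max
and rg_min < Rg < rg_max.  The package is written around the four-domain
folding enzyme ER-60/ERp57 (domains a, b, b', a' in a twisted U-shape, with
redox-active CGHC motifs in the edge domains a and a'), but every component
is generic over a `DomainDefinition`.

## Coarse-grained model

Each residue is one bead at its CA position.  The potential is
native-referenced (Go-type) inside folded regions and deliberately
structureless in designated flexible loops:

* **Bonds** between chain neighbours, E = ½ k_b (r − r0)², k_b = 100 kBT/Å²,
  r0 from the reference structure.  Applied everywhere, including loops.
* **Angles**, nominal stiffness k_θ = 20 kBT/rad² at the native angle for
  fully folded triples and a weak generic term (5 kBT/rad², θ0 = 120°) for
  triples containing a flexible bead.  Both are evaluated as
  E = ½ k_cos (cos θ − cos θ0)² with k_cos = k_θ / max(sin²θ0, 0.1): this is
  harmonically equivalent near θ0 but remains finite at collinear
  geometries, which a harmonic-in-θ force (∝ 1/sin θ) does not.  The toy
  system's lattice-built domains contain exactly straight triples, so this
  robustness is not optional.
* **Dihedrals** E = k_φ (1 − cos(φ − φ0)), k_φ = 1 kBT, only for fully
  folded quadruples whose native inner angles are well away from collinear
  (sin θ ≥ 0.3); a degenerate reference makes the torsion undefined.
* **Native contacts**: 12-10 well E = ε[5(r0/r)¹² − 6(r0/r)¹⁰] with minimum
  −ε at the native separation, for bead pairs with |i−j| ≥ 4, native CA-CA
  distance ≤ 6.5 Å, and membership in the same folded unit.  The b and b'
  domains form one folded unit (their mutual arrangement is treated as
  fixed, consistent with the near-identity of the isolated and full-length
  b-b' crystal forms); no contacts connect a, b-b' and a', so the
  inter-domain geometry is controlled by the linkers, excluded volume and
  electrostatics only.  Default ε = 2.0 kBT: in a scan at 300 K
  (ε = 0.8/1.2/1.6/2.0 kBT over 3×10⁴ steps) the CA-level contact network
  only holds the domains folded (minimum native-contact fraction Q > 0.9)
  at 2.0 kBT; weaker wells let the toy domains melt, violating the
  folded-domain premise of the whole approach.
* **Excluded volume** E = ε_ev (σ/r)¹², σ = 4 Å, ε_ev = 0.2 kBT, between all
  pairs except chain neighbours (1-2, 1-3) and native-contact pairs.
* **Electrostatics**: Debye-Hückel screened Coulomb,
  E = l_B q_i q_j e^(−r/λ_D)/r in kBT units, with Bjerrum length
  l_B ≈ 7.1 Å (ε_r = 78, 300 K) and Debye length λ_D ≈ 7.9 Å at the default
  ionic strength 150 mM.  Flexible-loop charges follow the explicit rule
  (+1 per loop Lys, −1 per loop Asp/Glu); folded-region titratable residues
  (Lys/Arg/Asp/Glu) are charged only when surface-exposed by a burial
  proxy (≤ 14 neighbour CAs within 10 Å), with an `all-titratable` fallback
  mode.  Histidine stays neutral (pH 7.4).  The proxy replaces a
  surface-charge fitting procedure that cannot be reproduced from published
  information; it preserves the electrostatic character (charged exterior,
  neutral core) at the cost of per-residue accuracy.
* **Hydrophobic term** (optional, default off): a smooth −0.2 kBT well
  turning on below ~6 Å between beads of {A,V,L,I,M,F,W,Y,C}.  Off by
  default because no parameterisation is published for the reference
  setup; the toggle documents the gap.

Units: energies in kBT at 300 K, lengths in Å, bead mass 1, time in
√(mÅ²/kBT).  Temperatures other than 300 K scale kT = T/300.

## Dynamics

Langevin dynamics uses the BAOAB splitting with dt = 0.01 reduced time
units and friction γ = 0.5 (inverse reduced time).  At γ = 0 the scheme
reduces exactly to velocity Verlet, which the energy-conservation check
exploits (drift < 0.1% of |E| over 10⁴ steps at dt = 0.002).  Velocities
are initialised from the Maxwell-Boltzmann distribution; the sampled
kinetic temperature stays within 3% of the set point and its fluctuations
match equipartition.  Snapshots are saved every `save_interval` steps
(frame count = ⌊n_steps/save_interval⌋ per run).  Identical seed and
parameters give bitwise-identical trajectories.

The reference production protocol for the real protein is 40 independent
runs of 10⁸ steps saved every 5000 steps (8×10⁵ snapshots).  Everything in
this repository runs a desk-scale analogue (10⁴–2×10⁴ steps per run,
60-frame state ensembles, 130-bead toy); these sizes are the package's
documented defaults and are what the tests and the acceptance script use.

## SAXS

Model intensities use the Debye formula
I(q) = Σᵢⱼ fᵢ fⱼ sin(q rᵢⱼ)/(q rᵢⱼ) with uniform per-bead amplitudes by
default and no hydration layer.  When the screening target is itself
computed from bead models (as in the synthetic study), uniform beads keep
model and target on exactly the same footing; per-residue amplitudes are
available through `FormFactorModel`.  Guinier fits are linear least squares
of ln I on q², iterated until every included point satisfies
q·Rg ≤ 1.3 (the standard exp(−Rg²q²/3) form).  P(r) is the weighted
pairwise-distance histogram normalised to unit area, with Dmax the largest
pair distance.  chi2 between a model and a target with uncertainties is the
reduced form (1/(N−1))Σ[(c·I_m − I_t)/σ]² with the closed-form optimal
scale c and no additive offset; screening compares q ≤ 0.25 Å⁻¹ by default,
since the high-q tail of a CA bead model carries no information.

## Aggregate-corrected monomer extraction

Real SEC purification leaves a small oligomer fraction (~4 wt% dimer +
trimer) that inflates the apparent Rg.  Given the weight fractions (as an
AUC-style `MixtureSpec`), the extraction models each k-mer as a linear
array of k monomers: per-particle I_k(q) = I₁(0)·P(q)·S_k(q), with P the
iteratively refined normalized monomer shape and S_k the array structure
factor whose spacing reproduces the component's Rg (measured value if the
spec carries one, else the compact-growth model Rg_k = Rg₁k^(1/3)).  The
monomer forward intensity follows from I_obs(0) = I₁(0)Σ w_k M_k/M₁, and
the corrected curve is (I_obs − aggregates)/w₁, refined over two passes.
On synthetic data the zero-noise closed loop recovers the true monomer Rg
to < 0.1%; with the default noise model the residual error is dominated by
the ~1% statistical uncertainty of a Guinier fit on the synthetic grid, so
individual noise realisations can reach ~2%.

## Screening and geometry analytics

Every pooled snapshot is scored with its coordinate Rg (deterministic and
noise-free; a flag switches to Guinier-of-model) and chi2 against the
target.  Selection uses strict inequalities at both thresholds.  Domain
geometry uses equal-mass COMs over each domain's non-flexible beads — the
flexible linkers and the C-terminal tail are excluded because the tail
shows no correlation with the inter-domain descriptors.  The descriptors
are θ₁ = ∠(a,b,b'), θ₂ = ∠(b,b',a'), the signed four-COM dihedral
φ(a,b,b',a') (right-handed convention; the crystal-like reference renders
positive), and the edge-domain COM distance D(a,a').  Ensemble
visualisation superposes the b-b' CA beads of every model onto a reference
(Kabsch, proper rotation via SVD sign correction) and averages each domain
COM; the spread is the RMS scatter of per-frame COMs.  Histograms default
to 5° bins for angles, 10° for φ, 1 Å for D; 2-d maps are normalised to
unit total frequency before subtraction.

## Synthetic ground truth

The toy protein is four compact domain blobs (default 30 beads each) built
as cubic-lattice serpentine walks with exact 3.8 Å spacing — self-avoiding
and compact by construction, with no energy minimisation step — joined by
short flexible linkers and a flexible C-tail.  Domain COMs are placed
analytically (NeRF construction plus a 1-d root solve for the arm length)
so the built structure realises any requested (θ₁, θ₂, φ, D) essentially
exactly; the defaults are the domain geometry of the full-length ER-60
crystal structure (72.0°, 132.6°, 62.2°, 54.5 Å), so the default toy doubles as a synthetic
crystal surrogate.  A seeded 0.02 Å jitter breaks lattice symmetries.

Two sub-states are sampled with a harmonic COM-distance restraint on
D(a,a') (k = 1 kBT/Å², targets 60 and 48 Å by default, mimicking the
more-expanded oxidized versus reduced forms); restraint metadata is stored
on the trajectory so production paths can recognise restrained data.
Observations are synthesized as the ensemble-averaged monomer Debye curve
mixed with dimer/trimer profiles from rigid side-by-side copies of the
median-Rg frame (96/3/1 wt%), then degraded with multiplicative Gaussian
noise of relative SD σ(q) = 0.01 + 0.05q on a 150-point grid over
0.01–0.30 Å⁻¹.

What the generator does **not** emulate: atomic form factors and hydration
scattering, instrument smearing, inter-particle structure factor,
concentration effects, realistic aggregate shapes, and any
redox-state-dependent force field (as in the real protocol, the two
states differ only through the target profile used for screening — here
via the restraint that generated each target).  Passing tests therefore
demonstrate that the pipeline's mathematics and inference loop are
correct and self-consistent, not that the force field is predictive for
real proteins.

## Limitations and open choices

* Crystal-structure worked examples run on the synthetic surrogate unless
  the user supplies the real PDB files (`analysis/06_crystal_structures.py`);
  the package does not redistribute PDB entries.
* The b/b' geometric split defaults to residue 232/233 of the mature ER-60
  numbering (standard ERp57 domain annotation) and is configurable; the
  choice shifts the crystal-row angles by a few degrees.
* Contact detection is CA-level with a 6.5 Å cutoff rather than all-atom.
* The chi2 definition, Guinier window rule, q-range restriction and the
  (N−1) normalisation are stated package conventions; other software makes
  different choices and yields numerically different chi2 values for the
  same curves.
* Sequence masses use standard average residue masses (free glycine
  75.07 Da); each disulfide bond subtracts 2×1.008 Da.
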