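# Methods

This note documents the models, parameter choices and limitations of each
stage. Units throughout: lengths in Å, energies in kcal/mol, charges in e,
potentials in kT/e at 298.15 K, frequencies in GHz.

## Candidate selection

Candidates are aligned, non-gap, differing columns of a two-sequence
donor/acceptor alignment, numbered in acceptor coordinates via a gap-skipping
column map (configurable start offset; crystal numbering + 15 = full-sequence
numbering for the spermine-synthase case).

Filters, in order:

1. **Surface exposure.** The selection module consumes a per-site boolean;
   the structure module produces it as relative SASA ≥ 0.25 against a
   bundled Gly-X-Gly maximum-area table. The 0.25 default is our choice —
   no criterion is published for this protocol — and is configurable.
2. **Conservation.** A column is conserved when its modal residue frequency
   is ≥ 0.9 (configurable); conserved candidate columns are dropped.
   Non-conserved sites with a conserved column within ±2 columns are
   flagged `near_conserved` — a ranking preference, not a filter, matching
   the protocol's stated preference for non-conserved sites neighboring
   well-conserved ones.
3. **Manual exclusions.** Bespoke judgments (e.g. dropping a site adjacent
   to a disease-associated position near the active site) are expressed as
   a config exclusion list rather than re-implemented heuristics; the
   default list contains site 149.
4. **Frequency rule.** A candidate survives when the donor residue reaches
   ≥ 50% frequency in the homolog MSA. The rule deletes strictly-below-
   threshold candidates, so an exact 50.0% survives. The denominator
   includes gapped sequences: the published per-site counts sum to the full
   500-sequence panel including a gap category, which settles the
   otherwise-ambiguous convention.
5. **Coevolving-partner rescue.** For each survivor, the remaining
   (pre-frequency) candidates are scored by mutual information with
   average-product correction, gaps treated as a 21st symbol. The published
   protocol never states how "correlated" was computed; MI+APC is our
   stand-in, chosen because it is the field-standard coevolution statistic
   and testable against a permutation null. The default threshold is
   mean + 4·sd of 200 column-shuffle permutations (seeded, deterministic);
   an absolute threshold can be supplied instead. Alignments under 30
   sequences are rejected as statistically unreliable. Partners enter the
   final list alongside the survivors; ordering is ascending site number
   everywhere.

## Structures and mutagenesis

PDB files are parsed with gemmi; alternate locations keep the
highest-occupancy conformer. Radii are a Bondi-style element table
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.10); partial charges are a coarse
documented set: backbone amide dipole (N −0.30, H +0.30, C +0.50, O −0.50)
plus formal charges on ionizable side-chain termini and small dipoles on
polar groups. Neutral residues sum to 0 e, Asp/Glu to −1, Lys/Arg to +1.

Biological-unit selection extracts a requested chain pair and reports all
inter-chain atom pairs closer than r_vdw(i)+r_vdw(j)−0.4 Å — the same scan
that distinguishes a clash-ridden crystal-contact pair from a clean
biological dimer. Domain truncation removes a closed residue range (default
2–109, the dimerization N-domain, far from all mutation sites) from every
chain.

Mutant building keeps the backbone (N, CA, C, O, amide H) fixed and grafts
the new side chain from ideal-geometry residue templates (CCD component
coordinates shipped with biotite), superimposed on the local backbone by a
three-point Kabsch fit. χ1/χ2 are scanned on a 15° grid and the rotamer
with the fewest hard-sphere clashes (0.4 Å tolerance) against the rest of
the structure is kept; ties break toward the first grid point, so the
builder is deterministic. χ3/χ4 keep template values. This is adequate for
the solvent-exposed sites the cascade targets; it makes no claim for buried
sites, and a wild-type mismatch between spec and structure is a hard error
(it almost always indicates a numbering mix-up).

Tripeptide segments (site ± 1) are extracted with parent coordinates — no
refitting — and their uncapped termini stay neutral, so no spurious charges
appear in the unfolded-state proxy. At chain termini the two existing
residues are returned and flagged.

Polar hydrogens: backbone amide H in the peptide plane; hydroxyl/thiol H at
ideal bond length and angle with the torsion scanned at 10° to approach the
nearest acceptor. Hydrogen-bond geometry reports the H···acceptor distance
and donor–H–acceptor angle, with a 3.5 Å classification cutoff.

### Solvent accessibility

Shrake–Rupley with a 1.4 Å probe and a 960-point Fibonacci lattice per
atom. The lattice is oriented per atom by the principal axes of its
occluders' unit directions: this makes per-atom areas independent of the
global orientation (the total energy is rigid-motion invariant to ~1e-13)
and exactly additive for well-separated components (the binding
non-interacting limit is exact). The frame is undefined only for perfectly
axisymmetric neighborhoods, which do not occur in practice. Doubling the
lattice changes a helix total by ~0.01%.

## Energy function

A deliberately simplified, self-contained MM+GB evaluator that preserves
the *bookkeeping* of a multi-force-field stability protocol while staying
desk-scale. Its absolute magnitudes are not comparable to published
force-field energies, and the package never claims otherwise.

* **Bonded:** harmonic restraints on detected covalent bonds (distance
  criteria: heavy–heavy < 1.95 Å, 2.2 Å with sulfur, X–H < 1.25 Å) with the
  input geometry as reference length and k = 300 kcal/mol/Å².
* **van der Waals:** Lennard-Jones 12-6, element-based well depths,
  r_min = 2·r_vdw; 1-2/1-3 exclusions, 1-4 scaled by 0.5.
* **Coulomb:** 332.0636·q_iq_j/(ε_in·r), ε_in = 1.0, same exclusions.
* **GB polar:** Still pairwise formula
  f_GB = √(r² + α_iα_j·exp(−r²/4α_iα_j)) with fixed Born radii
  α_i = r_vdw. The isolated-ion limit then reproduces the Born formula
  exactly, and the term vanishes as ε_out → ε_in. Foregoing descreening
  keeps the term analytic, differentiable and honest about its coarseness.
* **Nonpolar:** γ·SASA, evaluated at reporting time only (not part of the
  minimized objective, which keeps the gradient exact).

Three parameterizations (`setA`/`setB`/`setC`) differ in LJ depth scaling
(1.0/0.85/1.15), radius shifts (0/+0.05/−0.05 Å) and γ
(0.005/0.007/0.006 kcal/mol/Å²). Energies are averaged across
parameterizations and across the two monomers exactly as a three-force-field
protocol averages its results.

**Minimization** is L-BFGS on the differentiable terms with an RMS
per-atom gradient tolerance of 0.01 kcal/mol/Å and a 5000-iteration cap;
clashed inputs are first relaxed for 50 iterations under a soft-core vdW
(r_eff = √(r² + (σ/2)²)). The line search guarantees non-increasing energy
across accepted steps; an already-minimized input returns unchanged.

### ΔΔG bookkeeping and sign conventions

With potential energies, "the mutant is more stable" means its folded state
sits *lower* relative to its unfolded reference, so the stability change is
reported as

ΔΔG = [G(folded, WT) − ΣG₃(WT)] − [G(folded, mut) − ΣG₃(mut)],

positive = stabilizing, and swapping WT/mutant negates it exactly. The
binding change ΔΔG(binding) = G(dimer) − G(C) − G(D) is evaluated per
state and differenced as ΔΔΔG = ΔΔG(binding, WT) − ΔΔG(binding, mutant),
making positive values mean increased dimer affinity — the convention the
result tables use. Monomers are rigidly extracted from the dimer by
default; independent re-minimization is a config switch (the original
protocol does not say which was done).

The two-parameter adjustment is an affine least-squares fit of
(raw, adjusted) pairs — the published footnote says only "two parameters",
and an affine map through the two printed single-mutant pairs reproduces
the printed pair-mutant prediction to the printed precision, which is the
evidence for the functional form. Additivity reports the sum of single
effects vs the combined mutant with a relative-deviation verdict (default
tolerance 5%). Binding classifications use a ±2.0 kcal/mol neutral band
(configurable; the published analysis defers the band to prior work). pKa
tables are consumed as external input only; shifts are element-wise
mutant − WT, with residues missing from either table reported as absent,
never as zero.

## Electrostatics

Finite-difference linearized PBE,
∇·(ε∇φ) − ε_s·κ²(r)·φ = −4πC·ρ, with φ in kT/e and
C = e²/(4πε₀kT·Å) = 332.0636/(R·T) ≈ 560.5 at 298.15 K. Defaults follow the
published run: 1 grid/Å, 70% fill, ε 2/80, 0.15 M (κ⁻¹ ≈ 7.9 Å), probe
1.4 Å, Stern 2.0 Å.

Discretization: 7-point stencil with face dielectrics sampled at face
centers against probe-inflated atom spheres (no reentrant molecular
surface — a documented simplification relative to DelPhi-class solvers);
κ² is zeroed inside solute + Stern layer; charges spread trilinearly;
Dirichlet boundary from per-charge Debye–Hückel monopoles. The system is
symmetric positive definite and solved by Jacobi-preconditioned conjugate
gradients (rtol 1e-8, cap 10,000 iterations); non-convergence raises. A
`center`/`box_size` override pins the cube so wild-type and mutant maps
share a grid; difference maps refuse mismatched geometries rather than
resample.

Against closed forms, the solver is within 0.7% of Coulomb (uniform ε) and
within 1% of the Debye–Hückel dielectric-sphere exterior at 6–10 Å on a
1 Å grid — comfortably inside the 3–5% acceptance bands.

CUBE output follows the Gaussian layout (header and axes in bohr,
1 Å = 1.8897261 bohr, values z-fastest); non-orthogonal axes are rejected
on read. Patch statistics take a residue list per patch (the published
"path A/B" regions are defined only pictorially, so patches ship as
config) and summarize the difference map over solvent-side grid points
hugging those residues' surfaces.

## Elastic network model

Cα nodes, springs between pairs within 15 Å, uniform γ = 1.0 kcal/(mol·Å²)
("distance weight 0" = weight exponent 0). The 3N×3N Hessian of
γ/2·Σ(|r_ij|−|r⁰_ij|)² has six exact zero modes for any non-collinear
structure; collinear node sets are rejected (degenerate rotations). Dense
symmetric eigendecomposition is used throughout (the systems here are
small; 3N ≤ 3000 would still be fine).

Frequencies: ν = (1/2π)·√(γλ/m) with γ converted at 0.69477 (N/m per
kcal/mol/Å²) and m = 110 Da (average residue mass) per node. The published
mode table came from a webserver whose mass/unit convention is not
recoverable, so absolute GHz values are not comparable; only the
arithmetic force-field averaging of the printed values is reproduced.

## Synthetic data

The MSA generator samples 500 sequences over 221 columns (sites 140–360).
Columns at the nine candidate sites follow fixed distributions: the four
engineered sites use the published 500-sequence profiles (with an 'X'
category absorbing unlisted residues); the other candidate sites use
constructed profiles that exercise each deletion rule (donor residue below
50%, gap-dominated column). The 175/178 pair is sampled jointly via a
comonotone coupling of its two marginals — strongly associated yet exactly
marginal-consistent — so the rescue stage has a real signal to find.
Background columns are 95%-conserved around a per-column reference residue.
The reference (acceptor) sequence is row one; the donor sequence differs at
the candidate sites plus two buried decoys for the surface filter. All
generators are pure functions of (spec, seed).

What the generator does *not* emulate: phylogenetic correlation between
sequences, indel structure beyond single gap categories, and any coupling
beyond the one designated pair. Passing the recovery test therefore shows
the cascade's statistics behave correctly under the stated profiles — not
that the thresholds are optimal for real, phylogenetically structured
alignments.

Toy structures: ideal α-helices (φ = −57°, ψ = −47°, standard backbone
internal coordinates, per-residue net charge zero), two-domain dimers with
an exact cleft width, charged spheres and Cα spring chains carrying exact
parameters for the analytic oracles.

## Problem sizes and determinism

The test suite runs toy systems (≤ ~100 atoms, ≤ 70 k grid points,
500×221 alignments) and completes in about a minute; the acceptance script
repeats the selection-recovery experiment over 100 seeded alignments and
finishes in under two minutes. Every stochastic step takes an explicit
seed, and identical config + seed reproduces byte-identical pipeline
reports.

## Known limitations

* The energy function is a teaching-grade surrogate: no torsional terms, no
  descreened Born radii, coarse charges. Only *differences* under its own
  bookkeeping are meaningful.
* The rotamer builder scans χ1/χ2 only and optimizes a clash count, not an
  energy.
* The PB dielectric boundary is a union of inflated spheres, not a
  molecular (reentrant) surface; expect boundary-layer differences from
  DelPhi-class solvers near the surface.
* The MI+APC coupling statistic and its permutation threshold are a
  documented stand-in for an unpublished choice.
* Published absolute energies (force-field kcal/mol tables) and webserver
  GHz values are consumed as bookkeeping fixtures, never recomputed.
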