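# Methods

## Model and assumptions

The package treats the hydrophobicity organization of a folded unit as a
distribution-comparison problem. Three assumptions underlie it:

1. A residue's spatial influence can be summarized by one point — the
   centroid of its heavy atoms — carrying a scalar intrinsic
   hydrophobicity. No atom-level energetics, solvent accessibility, or
   secondary structure enter the model.
2. Folding in bulk water drives a globule toward a micelle-like state
   whose idealized hydrophobicity density is a separable 3D Gaussian over
   the molecular body (distribution **T**). The observed counterpart
   (**O**) is built from pairwise inter-residue hydrophobic contacts
   weighted by the Levitt distance polynomial.
3. Departures from the water ideal can be expressed as a one-parameter
   family `M(K) ∝ T + K·(T_MAX − T)_n`: the water field mixed with its
   normalized complement. K = 0 is pure water; growing K flattens and then
   inverts the preference for a central core.

All four profiles (T, O, uniform R, M) are normalized to unit sum over the
residues of the analysis unit, so Kullback–Leibler divergences (base-2
logarithms, bits; the `0·log 0 = 0` convention for zero observed entries)
are well defined. The statistic `RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))`
locates O between the core ideal (RD = 0) and the coreless uniform state
(RD = 1), with RD = 0.5 the classification boundary.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| hydrophobicity scale | Kyte–Doolittle, rescaled to [0,1] | — | intrinsic residue hydrophobicity in O |
| interaction cutoff `c` | 9.0 | Å | contact range of the Levitt polynomial |
| sigma rule | `std` (per-axis coordinate std) | — | width of the Gaussian body |
| sigma floor | 1.0 | Å | guards planar/linear units from collapse |
| K grid | 0–10, step 0.01 | — | exhaustive search range for the field fit |
| interface threshold | 9.0 | Å | P-P contact distance on effective atoms |

The literature this family of measures comes from does not pin down the
hydrophobicity scale or the sigma convention, and both shift the absolute
RD/K numbers appreciably. They are therefore explicit configuration, every
record carries a full provenance stamp (scale, cutoff, sigma rule, grid),
and `fodm.sweep.sensitivity_sweep` recomputes a unit under all bundled
scale × sigma-rule combinations to find which convention best matches an
externally printed value.

**Sigma convention.** Three rules are provided: `std` (per-axis standard
deviation of the oriented coordinates — the maximum-likelihood sigma if
the body were itself Gaussian), `extent3` (max |coordinate|/3, the
"three-sigma coverage" convention), and `extent6`. The package default is
`std`: on the idealized reference units the generators produce (below), it
is the only bundled rule that places micelle-like units below RD = 0.5 and
inverted units above it, which is the behavior the classification boundary
is meant to encode. `extent3` makes T substantially more peaked than any
contact-derived O profile and pushes even perfectly ordered micelle-like
point clouds to RD ≈ 0.5.

**K search.** The fit is an exhaustive grid scan, not a continuous
optimizer: the objective can be nearly flat for weakly structured T, and a
scan is deterministic and exactly reproducible at the reported precision.
Ties break toward smaller K. Tables report K at 0.1 resolution; the grid
value is stored. A uniform T has no complement; K is then undefined and
reported as 0 with a `degenerate_field` flag rather than a fake fit.

## Analysis granularities

*Individual* units get their own orientation, sigmas and profiles.
*Component* units inherit the parent's Gaussian and O, restricted to the
subset's residues and renormalized (restriction on the full parent is the
identity, which is regression-tested). Interface splits (P-P vs no P-P)
use component-style restriction of the target's own profiles, with a
residue counted as P-P when its effective atom is within the threshold
(≤, so a pair at exactly the threshold is a contact) of any partner
effective atom. Empty classes are reported as absent (a dash), never 0.
Complex-level reports emit the whole complex, each chain in both modes,
and any named partitions (e.g. a β-sheet stem or helical tentacles of a
hexameric chaperone, whose residue ranges are configuration data, not
computed).

## Synthetic data: what it emulates and what it does not

The generators produce point-cloud "structures" with controlled
hydrophobicity ordering: `make_micelle` samples n points uniformly in a
20 Å ball and assigns h by radial rank (1 at the center, linearly down to
0 at the surface); `make_inverted` flips the ranking; `make_shuffled`
permutes it; `make_field_profile` draws a geometry, computes T, and sets
O := M(T, K_true), optionally with multiplicative log-normal noise before
renormalization (profiles stay positive and unit-sum). Defaults (n = 100,
radius 20 Å) keep typical spacing well inside the 9 Å cutoff, so O is
never degenerate. All generators are pure functions of (parameters, seed).

These units emulate the *ordering* regimes of the model — water-driven
burial, inverted (membrane-like) exposure, and field-generated profiles —
not proteins: there is no chain connectivity, no realistic packing
density gradient, no sequence composition, and the radial h-ladder is
linear rather than matched to any physical transfer free energy. Passing
tests therefore demonstrate that the pipeline measures hydrophobicity
ordering correctly and recovers a known field parameter; they do not
certify the absolute RD/K values of real deposited structures, which
additionally depend on the scale/sigma conventions above.

## Numerical choices and degenerate inputs

- T is computed in log space and shifted by its maximum before
  exponentiation, so far-flung residues underflow gracefully.
- The Levitt weight is exactly 0 at r = c; a unit whose only contacts sit
  at the cutoff has an identically zero O and raises a degenerate-profile
  error rather than returning NaNs.
- Principal-axis orientation leaves axis signs arbitrary; every downstream
  quantity is sign-invariant, and RD/K are invariant under rigid motion of
  the input to ≤ 1e-6 (tested to machine precision in practice).
- O may contain zeros (isolated residues); D_KL(O|·) handles them by the
  zero-mass convention. T and M are strictly positive by construction, so
  support errors cannot arise in the standard pipeline.
- Alternate conformers resolve to the highest-occupancy atom; modified
  residues map to their parent standard residue (e.g. MSE → MET) or are
  rejected by name.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic units:
50 seeds × 100 residues for the classification contracts, 50 noiseless
plus 201 noisy trials (n = 100) for K recovery, and oracle comparisons on
units of up to 50 residues. These sizes give stable means (generator RD
means move by < 0.03 across seed bases) while keeping a full run in
seconds.

## Known limitations

- Absolute RD/K values for deposited structures depend on unstated
  conventions of the source literature; only qualitative classifications
  (which side of RD = 0.5) should be compared across implementations
  without a convention sweep.
- The effective-atom reduction discards side-chain orientation; interfaces
  defined on centroid distances are coarser than atom-contact definitions
  (a 4.5 Å heavy-atom alternative is configurable).
- No in-silico folding under the M field: the package analyzes given
  coordinates only.
- The stem/tentacle partitions of chaperone complexes are user-supplied
  residue ranges; the package does not assign secondary structure.
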