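# Methods

## Model

The Electronegativity Equalization Method determines partial atomic
charges from a molecule's 3D geometry by requiring that the effective
electronegativity of every atom equalize at a common molecular value χ̄
while the charges sum to the total molecular charge Q. For atom *i* of
type *t(i)*:

    A_t(i) + B_t(i)·q_i + κ · Σ_{j≠i} q_j / R_ij = χ̄,     Σ_i q_i = Q

Equivalently, the charges minimize the quadratic charging energy
E(q) = Σᵢ (Aᵢqᵢ + ½Bᵢqᵢ²) + ½κ Σ_{i≠j} qᵢqⱼ/R_ij subject to Σq = Q;
the equalization equations are exactly the stationarity conditions of
this constrained minimization, which is what the test suite's
independent null-space quadratic-programming oracle verifies.

Assumptions and conventions:

* distances are in ångström throughout; charges in elementary-charge
  units; A, B, κ share one consistent (arbitrary) unit system. No unit
  conversion happens anywhere.
* an **atom type** is the element symbol plus the maximal bond order
  among the atom's explicit bonds. Aromatic SDF bonds (type 4) are
  normalized to order 2 at parse time, so ring atoms land in the X2
  types. No aromaticity or bond-order perception is ever run — only
  explicit annotations are trusted; Kekulé-encoded rings keep their
  written orders. Isolated atoms have no multiple bond and default to
  order 1.
* hardness B must be positive; κ is positive; only *differences* between
  A values affect charges (below).

## Solver

Dense direct solve (LU with partial pivoting) of the bordered
(N+1)×(N+1) system, plus one step of iterative refinement; target
molecules are at most a few hundred atoms, so sparse machinery would
buy nothing. Guard rails, all of which refuse loudly rather than return
garbage:

* minimum interatomic distance 0.5 Å (configurable) — below any physical
  bond; closer pairs make the κ/R terms blow up and the matrix
  near-singular;
* condition-number ceiling 10¹⁰;
* verified residual ≤ 10⁻¹⁰·max(1, |Q|) and charge-sum check at the same
  tolerance.

## Gauge structure (why the fit is formulated the way it is)

Two exact invariances of the charge map matter:

1. **Shift gauge.** Adding a constant to every A shifts χ̄ by the same
   constant and changes no charge. Only A-differences are physical.
   In the regression this appears as a rank-1 null space (uniform shift
   of all A and all χ̄); the minimum-norm least-squares solution is taken
   as the canonical representative. Any rank deficiency *beyond* that
   one dimension indicates genuinely confounded types (e.g. a type whose
   atoms all carry the same reference charge) and is reported as a
   warning naming the types involved.
2. **Scale gauge.** Multiplying A, B, κ and χ̄ jointly by c > 0 rescales
   every equation and leaves the charges unchanged. Consequently the
   overall parameter scale — and with it the absolute value of κ — is
   *not identifiable from charges*. Moreover, the electronegativity-space
   regression is linear in κ: its minimum-norm solution at κ₂ is exactly
   (κ₂/κ₁) times the solution at κ₁, so the charge-space quality of the
   refitted parameters is exactly flat along κ, noiseless or noisy. The
   recorded κ trace of every fit shows this flatness (variation at the
   10⁻¹⁵ level, pure floating-point jitter).

   The package therefore fixes the scale by convention: **fitted sets
   are reported in the scale where the mean fitted hardness B equals
   1**, and the synthetic generator emits its ground-truth sets in the
   same canonical scale. Under this shared convention, parameter
   recovery (κ, B absolutely; A as differences) is well-posed and, on
   noiseless in-model data, exact to machine precision. User-supplied
   parameter files are never rescaled — the convention applies to the
   output of the fitter only.

## Parameterization procedure

1. Build the per-atom design once: unknowns {A_t, B_t per type} ∪
   {χ̄_m per molecule}; row for atom i: A + B·q_ref + κ·S_i − χ̄ = 0 with
   S_i = Σ_j q_ref_j/R_ij. Types with fewer than `min_atoms_per_type`
   atoms (default 10 — a type should never be fit from a handful of
   atoms) abort the fit with the offending type list.
2. Scan κ on a coarse grid (default 0.05–1.50, step 0.05, spanning
   published EEM κ values), refit at each point (exact scaling of the
   single factored base solution), and score **in charge space**: the
   candidate set is pushed through the full EEM solver on every training
   molecule and pooled R² (default) or RMSD against the references is
   the objective. Regression residuals are never reported as quality.
   Molecules whose system is singular at a candidate are excluded and
   counted; above 10 % exclusions the candidate is invalid. Ties break
   toward smaller κ.
3. Golden-section refinement around the best grid point to
   `refine_tol` (default 10⁻⁴), every evaluation appended to the trace.
4. Project the winner to the canonical scale (a pure gauge move that
   provably leaves the objective unchanged — it also makes the final
   parameters independent of where the flat search happened to stop,
   hence deterministic). Reject the set if any fitted B ≤ 0.
5. Recompute the reported quality by a full EEM re-solve
   (`validate_on_test_set` on the training input), so the quality figures
   are always the ones a user would measure.

## Quality metrics

R² (squared Pearson correlation), RMSD and mean absolute deviation Δ̄
between EEM and reference charges. The headline aggregation is **pooled
over atoms**: all covered molecules' charge vectors are concatenated and
one statistic triple computed — the convention that yields a single
quality figure per parameter set. Per-molecule statistics are available
as a clearly-labeled distribution view. Atoms of uncovered molecules are
excluded entirely. R² on a (numerically) constant vector is treated as
undefined and raised as an error, not coerced to 0 or 1.

## Coverage

A molecule is covered when every atom type resolves in the parameter
set, with the specificity rule: an exact key ("C2") beats an element
wildcard ("C", used by several legacy published sets for "all bond
orders"). Coverage and the solver share one resolution routine, so
"covered" is exactly "the solver raises no missing-parameter error".
SDF input is streamed record by record in constant memory; records that
fail to parse are tallied as *unreadable*, a third category, because
coverage is a statement about atom types, not file hygiene.

## Synthetic data generator

Emulates the study conditions with no external downloads:

* **composition**: atom types sampled from the relative frequencies of a
  large drug-like training collection (17 types, H1 dominating, then C2,
  C1, O2, O1, …); a rank-order test asserts the generated histogram
  keeps that ordering.
* **topology**: a spanning tree constructed so every atom's maximal
  incident bond order equals its sampled type order (order-3 atoms are
  chained with triple bonds, order-2 atoms with double bonds, order-1
  atoms attached by single bonds); singleton multi-order groups that
  cannot be realized are resampled to lower orders. Extra single bonds
  are added between geometrically close pairs — they never change a
  type. The graph is always connected.
* **geometry**: sequential stochastic embedding; bonded pairs at
  1.0–1.8 Å, all pairs ≥ 1.0 Å, bounded retries then a generation error.
  Geometry is *plausibility-only*: no valence rules, no torsional
  realism — EEM depends only on distances, types and Q, so passing tests
  demonstrate correctness of the machinery on EEM-consistent data, not
  accuracy on real chemistry or real QM charge schemes.
* **references**: exact EEM charges under a sampled canonical-scale
  ground truth; optional i.i.d. Gaussian noise (σ in e) projected back
  onto the conservation hyperplane so Σq = Q survives exactly.
* **determinism**: per-molecule RNG streams derived from one master seed
  (stable under changes of n_molecules); separate streams for parameter
  sampling and noise.

Default experiment sizes — 300 training molecules of 3–30 atoms for
recovery studies, 1000 molecules for conservation sweeps, 50 for the
energy-oracle comparison — were chosen as the smallest collections at
which every atom type in the 8-type recovery pool comfortably clears
`min_atoms_per_type` for any seed and the statistics are stable.

Known biases: with noisy references the hardness estimates suffer mild
errors-in-variables attenuation (the noisy charge multiplies B in the
regression), which propagates into the canonical-scale κ; at σ = 0.05 e
and 300 molecules the effect is at the percent level and the pooled R²
is unaffected.

## File formats

* **SDF**: MDL V2000 only, fixed-width fields; bond type 4 → order 2
  with the aromatic flag kept; `M  CHG` supersedes the legacy atom-block
  charge column; V3000 records rejected with a clear message. How
  external 3D generators encode aromatic rings (Kekulé vs type 4) varies;
  both are accepted, but Kekulé single bonds in rings are *not* promoted.
* **.eem parameter files**: `#` comments (`# key: value` becomes
  metadata), `kappa <float>`, then `<type> <A> <B>` lines; duplicates
  rejected with line numbers; deterministic sorted output with
  shortest-roundtrip floats, so write→read is exact. The dialect is this
  package's own, designed for hand-editability; converters to other
  solvers' formats can be layered on top.
* **charge files**: per-molecule block `<id> <N> <Q> <χ̄>` plus one
  `<index> <element> <type> <charge>` line per atom (9 decimals),
  blank-line separated.

## Limitations

* No 3D generation, protonation, conformer search or aromaticity
  perception — structures are taken as annotated.
* QEq/SQE variants, periodic systems and fragment charge constraints are
  out of scope.
* The published quality and database-coverage figures of real EEM
  parameter sets depend on QM reference charges and multi-million-
  compound databases; this package reproduces the *method* and verifies
  it property-by-property on synthetic data, and loads any user-supplied
  parameter sets for application to real collections.
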