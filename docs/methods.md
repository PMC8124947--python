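# Methods

## Model

The kernel energy method (KEM) reconstructs the energy of an n-fragment
system from single-kernel energies E_i and double-kernel energies E_ij:

    E_total = sum_{i<j} E_ij − (n−2) · sum_i E_i

The double sum runs over exactly all unordered kernel pairs. For a
strictly pairwise-additive potential the identity is exact:
sum_{i<j}(E_i + E_j + V_ij) − (n−2)·sum_i E_i = sum_i E_i + sum_{i<j} V_ij.
This is why the package carries a classical backend at all: it turns the
assembly layer into something that can be verified against a brute-force
all-atom evaluation to numerical precision, instead of being trusted.

The pairwise interaction energy is I_ij = E_ij − E_i − E_j, evaluated both
raw and counterpoise-corrected; the reported IE is their mean. The
protein–ligand IE sums the averaged ligand–residue I_ij only —
residue–residue pairs are computable but excluded from the total, matching
the kernel-selection convention in which the ligand is always the first
kernel and each active-site residue the second. The averaging is done per
pair and then summed; for a fixed pair set this equals averaging the raw
and CP sums, but it differs when pairs fail, and per-pair averaging keeps
the reported total consistent with the per-residue table it prints.

Failed pair energies (e.g. a QM job that aborts on an unfavourable
geometry) propagate as missing values: the pair lands in
`missing_pairs`, the result is flagged incomplete, and downstream pose
selection skips pose types without an IE rather than erroring.

## Structure preparation

* Alternate conformers: per atom group, the highest-occupancy altloc is
  retained; occupancy ties break to the alphabetically first altloc code.
  The operation is idempotent.
* Solvent is identified by residue-name whitelist (HOH/WAT/DOD/…,
  extendable), ions by a residue-name + single-atom rule. Both are removed
  by default; bridging waters can be retained by `remove_ions`/role
  adjustments, since whether any structural water should be kept in the IE
  calculation is a modelling choice, not something the pipeline can decide.
* The active site is every protein residue with at least one atom within
  the sphere radius (default 5 Å) of any atom of the center unit —
  minimum atom–atom distance, closed boundary (≤). The returned set never
  contains the ligand or the center unit itself. Atom–atom rather than
  centroid distance matches docking-software convention.
* PDB I/O goes through gemmi, SDF (V2000) through RDKit. Coordinates are
  Å throughout; there is no unit-conversion surface.

## Fragmentation and capping

Each active-site residue is one kernel; the ligand is one kernel (always
first). Backbone cuts are made at the peptide amide C–N bond between
consecutive residues — the standard fragment-based choice, keeping side
chains intact — and disulfide S–S bridges are cut likewise. Both sides of
a severed bond receive a hydrogen cap placed on the ray from the inside
atom toward the lost neighbour at a standard covalent length
(C–H 1.09 Å, N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å; overridable via
`CapRule`). Every original atom belongs to exactly one kernel; the
partition is asserted on every fragmentation. Formal charges come from
residue templates (ASP/GLU −1, LYS/ARG +1, neutral His, 0 otherwise);
unknown residues must be given explicit charges, never silently
neutralized. Multiplicity defaults to 1 (all systems handled are closed
shell).

## Energy backends

**Classical backend.** E = Σ_pairs [ 332.0636·q_i q_j / r +
4ε((σ/r)¹² − (σ/r)⁶) ] with Lorentz–Berthelot combination (arithmetic σ,
geometric ε). No cutoffs or switching: exact pairwise additivity is the
point. Caps participate as real atoms; uncapped parameters default to a
generic hydrogen type (q 0, σ 2.5 Å, ε 0.03 kcal/mol). Counterpoise
correction is degenerate without basis sets, so pair records report
e_cp ≡ e_raw — which is itself used to validate the averaging plumbing.
Coulomb constant 332.0636 kcal·Å·mol⁻¹·e⁻²; Hartree→kcal/mol 627.5095.

**External-QM interface.** `write_counterpoise_job` emits a two-fragment
counterpoise input in the Gaussian dialect (route line with the level of
theory and `Counterpoise=2`, combined-then-per-fragment charge/multiplicity
line, fragment-tagged atom lines, caps inside their kernel's fragment);
byte-stable for identical input. `parse_counterpoise_log` extracts raw and
corrected complexation energies (Hartree → kcal/mol) and requires a
normal-termination marker; anything unparseable becomes a `failed` record,
never an exception. Records parsed from logs carry complexation energies
directly and are marked as such (`is_complexation`), so the IE assembly
handles both the total-energy convention of the classical backend and the
difference convention of counterpoise output. The packaged example logs
are synthetic (written by this package's log emitter; no QM program is
run here).

## Pose handling

RMSD is the in-place heavy-atom root-mean-square displacement — no
superposition — because the quantity of interest is where the ligand sits
in the site, not conformer similarity. Hydrogens in a mapping are an
error. Cross-ligand comparisons require an explicit user-supplied atom
correspondence; there is no automatic maximum-common-substructure
inference (silent mis-mapping is worse than asking), and no
symmetry-equivalent-atom correction (known limitation).

Published orientation-type groupings of docked poses appear to have been
done by inspection; as a reproducible stand-in the package uses greedy
leader clustering: poses in descending fitness order, each joining the
first type whose representative is within the threshold RMSD (default
2.0 Å, aligned with the correctness cutoff) or founding a new type. Type
indices therefore order by the founding representative's fitness. The
best pose type per method is the max-fitness representative (fitness) or
the most negative averaged IE (IE), skipping missing IEs; ties go to the
lowest type index and are logged.

## Adjudication and ranking

A method's nominated type is correct iff its RMSD to the crystal ligand
geometry is ≤ the cutoff (default 2.0 Å). Summaries report integer
percentages (round-half-up, so 6/7 prints 86%). Rankings: IC50 ascending,
IE ascending, fitness descending; ties share the mean rank. Rank
agreement defaults to Spearman (Kendall tau available) and is reported as
a percentage together with the method label, because published percentage
correlations of this kind rarely state their measure. IC50 uncertainties
are carried for display but ignored in ranking.

On the packaged tables, Spearman reproduces the published best-pose
agreement for CDK2 (64.3%) and its Type-1 restriction (71.4%), and the
ERβ best-pose values (30.4% IE, 17.6% fitness) — computed by
`kemlead rank`, not asserted in tests, since the original measure is
unspecified.

## Synthetic data

The generator emulates a redocking study at desk scale: `n_residues`
(default 6) toy residues of 4 heavy atoms on a 6 Å shell around a
6-atom ligand; charges bounded by |q| ≤ 0.5 e, σ ∈ [2.5, 3.5] Å,
ε ∈ [0.05, 0.3] kcal/mol; all atoms pairwise ≥ 1 Å apart and
ligand–residue contacts kept at van der Waals distance (≥ 3.6 Å).
Binding is attractive by construction, as in a real pocket: each
residue's contact atom takes a charge opposing its nearest ligand atom,
and the residue's charge vector is sign-flipped/scaled (both
neutrality-preserving) until its Coulomb term with the ligand is a clear
attraction (4–8 kcal/mol target, within the charge bound). Units are net
neutral, so a displaced ligand sees only weak multipole tails.

Pose sets plant 3 orientation types × 10 poses (the 30-poses-per-ligand
docking protocol): type 1 is the bound geometry; other types are rigid
rotations plus a 15 Å translation (the spec-level constraint
displacement > 2·(jitter + 2 Å) keeps types unambiguous under the 2 Å
criterion); intra-type Gaussian jitter defaults to 0.3 Å per coordinate.
Fitness is an affine decreasing function of the true classical IE plus
Gaussian noise (σ default 1.0); IC50 = exp(5.0 + 0.05·IE + ε) nM with
log-scale noise σ as given. All generators take explicit seeds; there is
no hidden global randomness.

What the toy data does *not* emulate: real protein topology (residues are
disjoint blobs, so no severed bonds or caps arise in generated
complexes — capping is exercised on constructed peptide geometries
instead), polarization or many-body effects, QM-level energetics, and
conformational (rather than rigid-body) pose variation. Passing tests
therefore demonstrate the correctness of the assembly, clustering,
adjudication and ranking machinery under controlled conditions, not the
chemical accuracy of any particular energy model on real complexes.

## Numerical choices and problem sizes

* Exactness checks compare against an independent double-loop oracle at
  1e−9 relative tolerance; observed deviations are ~1e−15 (totals) and
  ~1e−11 (IE sums, where cancellation is larger).
* The exactness sweep uses 50 seeded complexes of 3–8 kernels; the pose
  recovery experiment uses 20 replicates with score noise set to zero —
  enough to exercise every code path while keeping the whole suite around
  a second.
* Degenerate inputs: single-atom kernels have zero energy; coincident
  atoms, overlapping kernels, empty mappings, empty sites and missing
  parameters all raise with the offending atom/pair named.
* The active-site boundary applies a 1e−9 Å epsilon so residues at
  exactly the radius are included despite float noise.

## Known limitations

No protonation/tautomer assignment, no metal-site chemistry, no
three-body KEM corrections, no automatic atom correspondence across
different ligands, no symmetry-aware RMSD, and docking scores are always
ingested, never computed. QM energies enter only through job files and
logs; running a QM program is out of scope.
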