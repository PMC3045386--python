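# Methods

## Scope and model

The package treats a comparative question in nucleocytoplasmic transport:
why one Ran-binding domain (RBD) binds RanGTP weakly while close structural
homologues bind tightly, and what that implies for the assembly and
disassembly of CRM1 export complexes. It operates purely on rigid-body
geometry of deposited or synthetic coordinates: superposition, contact
geometry, and grafting. No energetics, no flexibility, no rotamer
modelling. All geometry is heavy-atom (deposited crystal structures carry
no hydrogens) in Å, with author residue numbering preserved exactly as
deposited, because every residue-level statement in the source literature
uses author numbers.

## Superposition and rmsd_100

Superposition is the closed-form Kabsch least-squares fit of paired Cα
sets. Reflections are excluded by construction (the smallest singular
vector's sign is flipped when the correlation matrix has negative
determinant), so the reported optimum is over proper rotations only; a test
verifies optimality against a brute-force search over a dense Euler-angle
grid.

Raw rmsd grows with alignment length, so cross-table comparisons use

    rmsd_100 = rmsd / (1 + ln((N/100)^1/2)),

which rescales an N-residue alignment to an effective length of 100. The
denominator vanishes near N ≈ 13.5 and the normalization is unstable just
above that, so the implementation enforces a validity floor of N ≥ 20; the
analyses this package supports never normalize tiny alignments.

Residue equivalencing between low-identity domains is structure-based and
deterministic: a global sequence alignment (match +1, mismatch 0, gap −1 —
deliberately minimal, since it only seeds geometry) provides the initial
pairing; then the loop superposes on the current pairs, re-pairs
mutually-nearest Cα atoms within an inclusion cutoff (default 4.0 Å), keeps
the longest sequence-order-preserving subset, and repeats until the pair
set is a fixed point (≤ 50 iterations; cycles terminate on first revisit).
The cutoff is a configuration knob because the source analyses do not state
their inclusion criterion; published equivalent-position counts are
therefore checked as ranges, not exact values.

For NMR entries, comparisons are run against models 1, 10 and 20 and the
rmsd_100 values averaged, matching how the published comparison tables
handled multi-model depositions. Each chain of a multi-chain entry is a
separate comparison unit.

## Interface contacts

A contact is any intermolecular heavy-atom pair within 4.0 Å (the same
cutoff defines the "contact surface" residue set). Within that shell, a
pair is additionally typed, most-specific first:

- salt bridge: side-chain N of Lys/Arg/His against side-chain O of Asp/Glu
  at ≤ 4.0 Å;
- hydrogen bond: donor-capable element (N, O, S) against acceptor (N, O) at
  ≤ 3.5 Å, with no angle term (no hydrogens in the inputs); backbone vs
  side-chain is decided by the RBD-side atom's backbone flag, matching how
  per-residue contact marks are drawn in the field;
- otherwise van der Waals.

Configuration validation requires the H-bond and salt-bridge shells to lie
inside the vdW shell, so the type counts partition the contact list.
Because 4.0/3.5 Å are conventions rather than physical edges, headline
residue counts are reported together with their values at cutoff ± 0.25 Å
(`interface.cutoff_sensitivity`).

The class partition follows the "molecular embrace" of the Ran–RBD
interaction: class 1 contacts join the RBD N-terminal extension to the Ran
G-domain, class 2 the Ran C-terminal tail (linker, C-helix, DEDDDL motif)
to the RBD globular domain, class 3 the two globular domains. The effector
loop is part of the globular G-domain for classification purposes (its
contacts with the RBD β2 motif are class 3), but it keeps its own colour in
the region palette. Extension–tail pairs fit no class; they are surfaced as
"unclassified" rather than dropped. The RBD extension boundary and the
linker/C-helix boundaries on Ran are supplied as configuration with
documented defaults (DEDDDL fixed at 211–216 by sequence; effector loop
29–45, linker 177–187, C-helix 188–210 as implementer-chosen defaults —
the literature marks these boundaries only graphically).

Conservation mapping marks a template contact residue conserved iff its
structure-equivalenced residue in a query RBD has the same residue type;
residues with no equivalent are reported unknown, never silently treated as
non-conserved.

## Graft models and clashes

A graft places a query domain into a template complex by superposing mapped
core Cα atoms; partner chains keep their template coordinates bit-for-bit
(asserted by test). No side chains are built: where the query provides a
residue, its own side chain is carried; elsewhere the model records a
name-only threading (template position → query residue type), extended
after placement by mutual-nearest Cα pairing within 4 Å. Consequently,
clash analysis of threaded regions is restricted to backbone + Cβ by
default — conservative, since unmodelled side chains cannot be trusted to
clash. The clash cutoff (2.5 Å heavy-atom, well below vdW contact) is
reported alongside every severity so claims are cutoff-robust; severity is
monotone in the cutoff by construction.

The compromised-contact inventory annotates each template interface
contact as retained (same residue type threads to the position),
substituted (different type), or absent (no equivalent residue in the
query), and reports the compromised fraction. Accessions of third-party
ternary complexes used for clash analysis are configuration inputs, not
constants.

## Single-site ITC

The titration model is a perfusion cell of fixed volume V0: injecting dV of
syringe solution displaces dV of cell content, so total concentrations
update stepwise as M ← M(1−dV/V0), X ← X(1−dV/V0) + X0·dV/V0. After each
injection the complex concentration is the physical root of the 1:1
mass-action quadratic with n independent sites,

    [MX]² − (nM_t + X_t + K_d)[MX] + nM_t·X_t = 0,

evaluated in the numerically stable smaller-root form, and the integrated
heat of injection i is dH·V0·([MX]_i − [MX]_{i−1}(1−dV_i/V0)) plus a
constant dilution offset. Simulation and fit share this forward model;
correctness of the equilibrium solve is checked against an independent
bisection oracle, and heat bookkeeping against an analytic integral that
accounts for displaced complex.

The fit estimates (K_d, n, dH, offset) by Levenberg–Marquardt least squares
with data-driven initialization: n from the molar ratio at the steepest
heat change, dH from the first-injection heat in the tight-binding
approximation, offset from the titration tail, K_d from the cell
concentration at a starting c ≈ 5. K_d (not the association constant)
parameterizes the model to match how dissociation constants are reported
for this system; K_a is a derived property. Fits whose error bars are
missing or exceed the estimates (e.g. pure-offset data) are flagged
`converged=False` with diagnostics instead of raising. An optional flag
excludes the first injection, the common correction for syringe leakage
during equilibration; the default includes it.

Default design: 70 µM macromolecule in a 1.4 mL cell (nominal VP-ITC
volume), 800 µM injectant, 28 × 10 µL injections at 25 °C — the reported
experimental concentrations with an injection schedule chosen once inside
the reported 6–12 µL range to carry the titration to a molar ratio ≈ 2.5.
Ground-truth ΔH for simulations defaults to −10 kcal/mol, a typical
exothermic protein–protein binding enthalpy at 25 °C (the source experiment
does not report its fitted ΔH). Simulation noise for the headline recovery
runs is 2% of the first-injection heat (~1.3 µcal), a realistic integration
noise for heats of this magnitude.

## Synthetic data: what it does and does not show

The generators produce geometric test articles with exact ground truth:
ideal α-helices (1.5 Å rise, 100° turn, CA–CA 3.8 Å), copies perturbed by a
per-residue random field rescaled after removing the best-fit rigid
component until the planted optimal-fit rmsd is hit to within 0.5%,
two-chain structures whose contact inventory equals the planted list by
construction (each planted pair isolated by 25 Å), and chain pairs with an
exact clash count. Two-domain complexes carry seed-derived varied sequences
because a poly-Ala ideal helix is self-similar under a one-residue register
shift, which would make alignment-register tests ambiguous.

Passing on these fixtures demonstrates correctness of the geometry,
classification, bookkeeping and statistics — not robustness to the
pathologies of real crystallographic data (disorder, alternate
conformations beyond simple altloc selection, lattice contacts, coordinate
error). The checks that quantify those effects run on deposited PDB entries
and require the public archive to be reachable; they populate a local cache
on first use.

## Numerical and degenerate-input choices

- Altlocs: analyses use the highest-occupancy conformer, ties broken toward
  altloc 'A'; all conformers are retained on read/write.
- Kabsch rejects < 3 points and (near-)collinear inputs rather than
  returning an ill-conditioned rotation.
- Empty Cα selections raise instead of producing 0-atom superpositions;
  residues lacking a CA are skipped and reported.
- An empty interface or clash report is a valid result, not an error.
- Pipeline outputs are JSON with sorted keys and no timestamps, so byte
  hashes are reproducible for fixed config + seed.

## Known limitations

Sequence-order-independent (permuted) structure alignment is out of scope;
the equivalencer assumes both chains run through the fold in the same
order. Contact typing is purely distance-based — no angles, no buried
surface area, no waters, no energies. Grafting cannot predict new
stabilizing interactions, only the loss of template ones. The ITC module
fits a single-site model only and does not integrate raw power traces.
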