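# rbdcompare

Comparative structural analysis of Ran-binding domains (RBDs) — the
~120-residue pleckstrin-homology-fold domains through which RanBP1, RanBP2
and RanBP3 recognize the small GTPase Ran. The package implements the full
analysis chain by which a low-affinity RBD (RanBP3, K<sub>d</sub> ≈ 14 µM for
RanGTP) can be contrasted with the high-affinity RBDs (K<sub>d</sub> in the
low-nanomolar range) of the export-complex disassembly factors:

- **Superposition & normalized rmsd.** Kabsch least-squares rigid fits of
  paired Cα sets (proper rotations only), with the length-normalized score
  `rmsd_100 = rmsd / (1 + ln((N/100)^1/2))` so alignments of different length
  N are comparable, and iterative structure-based residue equivalencing
  (sequence-alignment seed, then mutual-nearest Cα re-pairing within 4 Å to
  convergence) for domains below ~25% sequence identity.
- **Interface classification.** Heavy-atom contact extraction at a 4 Å
  cutoff, geometric typing (van der Waals / side-chain H bond / backbone
  H bond / salt bridge), the three-class "molecular embrace" partition
  (class 1: RBD N-terminal extension ↔ Ran G-domain; class 2: Ran
  C-terminal tail ↔ RBD globular domain; class 3: globular ↔ globular), a
  Ran-region palette (G-domain, effector loop, linker, C-helix, DEDDDL
  motif 211–216), and conservation mapping of the contact surface through a
  structure-based alignment.
- **Graft models & clashes.** Rigid-body grafting of a query RBD into a
  template complex (no rotamer building; side chains are "threaded" by
  name), whole-complex alignment through a shared component, steric-clash
  detection (< 2.5 Å heavy-atom pairs), and an inventory of template
  interface contacts that are retained / substituted / absent after
  threading.
- **Single-site ITC.** Simulation and nonlinear least-squares fitting of
  isothermal titration calorimetry data under a perfusion-cell (VP-ITC)
  displacement model, parameterized by K<sub>d</sub>, stoichiometry n, ΔH
  and a per-injection dilution offset.

Synthetic ground-truth generators (ideal helices, copies perturbed to an
exact planted rmsd, planted contact inventories, known clash counts) make
every stage testable without downloading coordinates.

## Worked example

Generate an ideal 30-residue helix and a copy perturbed to a planted 1.0 Å
optimal-fit rmsd, then measure their structural correspondence:

```sh
$ rbdcompare fixtures make --kind helix --n-res 30 --seed 2 --out fx
$ rbdcompare fixtures make --kind perturbed_copy --target-rmsd 1.0 --n-res 30 --seed 2 --out fx
$ rbdcompare identity --a fx/helix_2.pdb:A --b fx/perturbed_copy_2.pdb:A
{
  "n": 30,
  "rmsd": 0.9999,
  "rmsd100": 2.5122,
  "identity_pct": 100.0
}
```

All 30 residues are equivalenced; the recovered rmsd matches the planted
1.0 Å, and the normalized score is larger than the raw rmsd because a 30-
residue alignment is rescaled to an effective length of 100.

Simulate a titration at a realistic design (800 µM injectant into 70 µM
macromolecule, 28 × 10 µL injections, 2% heat noise) and refit it:

```sh
$ rbdcompare itc-sim --kd 14 --n 0.93 --dh -10000 --noise 1.3 --seed 7 --out titration.tsv
$ rbdcompare itc-fit titration.tsv
{
  "kd_uM": 13.697177687629999,
  "n": 0.9063169960150701,
  "dH_cal_per_mol": -9816.727804809205,
  ...
  "converged": true
}
```

The fit recovers the generating K<sub>d</sub> = 14 µM and n = 0.93 within
the single-experiment uncertainty (the reported `kd_err` is ±1.7 µM at this
noise level and c ≈ 4.7).

A full pipeline run (comparison tables → interface report → graft/clash →
ITC) is driven from one YAML file: `rbdcompare run config.yaml`. Every
report embeds the cutoffs used, and identical config + seed reproduces
bit-identical outputs.

## Default thresholds

| Parameter | Default | Where |
|---|---|---|
| Contact / contact-surface cutoff | 4.0 Å heavy-atom | `interface.ContactCutoffs.vdw` |
| H-bond donor–acceptor cutoff | 3.5 Å (no angle term) | `interface.ContactCutoffs.hbond` |
| Salt-bridge cutoff | 4.0 Å (side-chain N⁺/O⁻) | `interface.ContactCutoffs.salt_bridge` |
| Equivalence inclusion cutoff | 4.0 Å Cα–Cα | `superposition.equivalence` |
| rmsd_100 validity floor | N ≥ 20 | `superposition.RMSD100_MIN_N` |
| Clash cutoff | 2.5 Å heavy-atom | `complex_model.DEFAULT_CLASH_CUTOFF` |
| Ran region boundaries | see `interface.RanRegionScheme` | config-overridable |

See `docs/methods.md` for the reasoning behind each choice and the model
assumptions.
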