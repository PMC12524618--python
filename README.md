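# dholoop

Survey machinery for the conformational state of the flexible active-site
loop in **dihydroorotase** (DHOase), the Zn-dependent amidohydrolase that
cyclizes *N*-carbamoyl-L-aspartate (NCA) to dihydroorotate (DHO) in de novo
pyrimidine biosynthesis.  The loop switches between **loop-in** (residues
contacting the bound ligand) and **loop-out** (oriented away from the
site); which state a crystal structure captures controls active-site
accessibility and makes or breaks docking-based inhibitor screening.  The
package is for structural bioinformaticians who want to classify and tally
these states reproducibly instead of by eye.

What it does:

* **Curated corpus** — a packaged transcription of the published survey of
  97 DHOase PDB entries (16 species, types I/II/III) with per-chain loop
  states and per-chain ligand assignments, expanded to 153 monomers and
  aggregated into species / type / ligand summary tables.
* **Coordinate classification** — per-monomer loop-in/loop-out calls from
  PDB/mmCIF coordinates: the *contact rule* (loop-in iff the minimum
  heavy-atom loop–ligand distance ≤ 4.0 Å) for ligand-bound chains, and the
  *apo reference rule* (core superposition onto a ligand-bound loop-in
  exemplar, then key-residue carbonyl-oxygen displacement) for apo chains.
* **Superposition** — sequence-alignment pairing, closed-form least-squares
  (Kabsch) fitting on Cα atoms, and TM-score
  `TM = (1/L_ref) Σ 1/(1 + (dᵢ/d0)²)` with `d0 = 1.24 (L_ref−15)^⅓ − 1.8`.
* **Dose–response** — IC50 from (concentration, % inhibition) points by a
  deterministic Hill fit or a 50%-crossing log interpolation, refusing when
  50% is never reached.
* **Synthetic structures** — generated monomers/corpora with exactly known
  ground truth (loop state, realized contact distance) for end-to-end
  validation without downloads.

## Worked example

```python
from dholoop import (
    expand_monomers, load_annotation_table, summarize, ligand_state_fractions,
)

records = load_annotation_table()          # 97 curated entries
monomers = expand_monomers(records)        # -> 153 per-chain records
summary = summarize(monomers)
print(summary.total_structures, summary.total_monomers,
      summary.total_in, summary.total_out, summary.ligand_bound_total)
# 95 153 86 67 117
print(summary.by_species["S. cerevisiae"].loop_in)   # 40  (always loop-in)
print(summary.by_species["E. coli"].loop_out)        # 24  (mostly loop-out)
print(ligand_state_fractions(summary, "MALIC_ACID")) # (100.0, 0.0)
print(ligand_state_fractions(summary, "FOA"))        # (26.67, 73.33)
```

95 analyzed structures expand to 153 monomers, 86 loop-in vs 67 loop-out;
117 monomers are ligand-bound.  Malate-bound monomers are loop-in without
exception, while 5-fluoroorotate leaves the loop out in 11 of 15 monomers —
the 4 exceptions are all *S. cerevisiae*, whose 40 monomers are loop-in
regardless of ligand.

Classifying from coordinates (here a generated structure with known truth):

```python
from dholoop import classify_monomer, make_monomer, read_structure, write_structure
from dholoop.synthetic import SyntheticSpec, motif_for_length

model, truth = make_monomer(SyntheticSpec(loop_state="in", target_contact_distance=3.0))
write_structure(model, "demo.pdb")
ann, cls = classify_monomer(read_structure("demo.pdb"), "A", motif_for_length(16))
print(ann.loop_state, cls.rule, round(cls.evidence.min_distance, 2))
# LOOP_IN contact 3.0
```

The IC50 of the flavonol myricetin against *S. cerevisiae* DHOase, from the
published inhibition points (22/35/43/71% at 2.5/5/10/20 μM):

```python
from dholoop import MYRICETIN_POINTS, fit_ic50
print(round(fit_ic50(MYRICETIN_POINTS, method="log_interpolation").ic50, 2))  # 11.89
```

The `examples/` directory holds one short script per capability; a thin CLI
(`dholoop survey|classify|compare|synth|ic50`) wraps the same functions for
shell use.

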