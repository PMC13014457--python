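# gluescreen

Molecular glues are small molecules that stabilize a protein–protein
interaction by binding in a pocket at or next to the complex interface —
the mechanism behind degraders such as lenalidomide, which glue an E3
ubiquitin ligase to a neo-substrate.  `gluescreen` mines protein dimer
structures (experimental or predicted) for **interface-adjacent pockets
(IAPs)**, screens those pockets against a library of ligand-bound template
pockets by sequence-order-independent structural alignment, transfers each
significant template's ligand into the target frame, and reports a
calibrated **binding precision** for every candidate glue.  It also ships
the benchmarking (recall / per-ligand precision / center-of-mass deviation)
and Tanimoto ligand-clustering machinery needed to evaluate such screens,
plus a fully synthetic fixture generator so the entire pipeline is testable
offline.

It is intended for structural bioinformaticians prototyping glue-discovery
screens and for anyone who needs a transparent, self-contained
implementation of interface-pocket mining and template-based ligand pose
transfer.

## Method

1. **Interface mining.** Residues of two chains interact when any pair of
   heavy atoms is within 4.5 Å.  A chain pair is a valid dimer when each
   chain contributes ≥ 5 interacting residues; a bound ligand is interface
   adjacent when it contacts ≥ 5 residues on *each* chain.
2. **Pocket detection.** A 1 Å grid is scanned for empty points (farther
   than vdW + 1.4 Å probe from every atom) that are buried — ≥ 9 of 14 rays
   (6 axial + 8 diagonal) hit protein within 8 Å.  Connected points form
   cavities; the library filter keeps cavities with ≥ 10 lining residues
   and volume ≥ 100 Å³.
3. **Pocket alignment.** Pockets are residue clouds (Cα + side-chain
   centroid + chemistry class).  Rigid superpositions seeded from
   chemistry-compatible residue triplets are refined by alternating Kabsch
   fits and one-to-one matching, scoring

   `PS = (1/min(|q|,|t|)) Σᵢ [1 + (dᵢ/d₀)²]⁻¹ · [1 − w + w·χᵢ]`,

   with d₀ = 3 Å and chemistry weight w = 0.3.  Significance is a Gumbel
   survival p-value, `p = 1 − exp(−exp(−(PS−μ(n))/σ(n)))`, with size-dependent
   location/scale fitted on random decoy pocket pairs.
4. **Screening.** Each interface-adjacent target pocket is aligned against
   every template (optionally skipping templates above a sequence-identity
   cutoff to either target chain); alignments with p ≤ 0.05 transfer the
   template ligand by the rigid transform, and a calibration table maps
   (p-value, identical aligned residues) to the predicted probability the
   ligand binds at ≤ 10 μM.  Predictions below precision 0.15 are dropped.

## Worked example

```python
from gluescreen import (ScenarioSpec, generate_glue_scenario, build_library,
                        screen_target, ScreeningParams, NullModel,
                        default_calibration_table)
from gluescreen.cli import DEFAULT_NULL_PATH

bundle = generate_glue_scenario(ScenarioSpec(rng_seed=42))   # planted pocket
library = build_library([bundle.template])                   # 1 template
preds = screen_target(bundle.target_dimer, bundle.truth_annotation, library,
                      ScreeningParams(), NullModel.from_json(DEFAULT_NULL_PATH),
                      default_calibration_table())
p = preds[0]
print(p.ligand_comp_id, f"p={p.p_value:.1e}", p.n_identical, p.precision)
```

prints

```
LIG p=7.5e-04 12 0.55
```

— the planted synthetic ligand `LIG` is recovered with pocket-similarity
p-value 7.5×10⁻⁴, all 12 aligned pocket residues identical, and predicted
binding precision 0.55 (i.e. a 55% chance of ≤ 10 μM binding under the
packaged placeholder calibration).  The placed pose lands on the ground
truth within numerical precision (center-of-mass deviation < 10⁻³ Å).

The same flow is available from the shell:

```bash
gluescreen simulate --out scenarios --n-scenarios 2 --seed 3
gluescreen build-library scenarios --out library
gluescreen screen scenarios --library library --out results
gluescreen benchmark --out bench --n-scenarios 6
```

## Layout

| module | role |
|---|---|
| `structure_io` | PDB/mmCIF parsing (gemmi), PDB writing, chain/ligand decomposition |
| `interface_mining` | residue contacts, dimer validity, IAP ligand calls |
| `pocket_detection` | grid buriedness scan, cavity volumes/lining, interface tags |
| `pocket_alignment` | pocket signatures, alignment, Gumbel significance |
| `glue_screening` | template library, identity filter, pose transfer, precision |
| `ligand_clustering` | path fingerprints, Tanimoto, leader clustering |
| `evaluation` | recall / precision / COM-RMSD benchmarking, cumulative curves |
| `synthetic_fixtures` | seeded generators with exact ground truth |
| `cli` | `gluescreen` subcommands: mine, build-library, screen, benchmark, cluster, simulate |

See `docs/methods.md` for the model assumptions, parameter defaults, and
the limits of what the synthetic fixtures demonstrate.
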