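# petscreen

In silico **reverse screening** for engineering PET-degrading enzymes.
The target system is PETase from *Ideonella sakaiensis* (catalytic triad
S160/D206/H237) bound to a tetrameric PET model substrate, but every
stage is generic: the physics engines (docking, MD, Poisson–Boltzmann
solvation) are replaceable inputs, and a synthetic-data module supplies
every input with planted ground truth so the whole pipeline runs and is
tested at desk scale.

## What it does

1. **Site nomination** — parse a multiple sequence alignment of the
   enzyme against homologous PET hydrolases, score per-column
   physicochemical conservation (0–11, Livingstone–Barton property
   counting), and nominate candidate mutation sites: loop residues
   facing the active site, plus helix/sheet residues with conservation
   strictly below a cutoff (default 6). Catalytic residues are never
   nominated.
2. **Alanine scanning (ASM)** — one Ala variant per candidate site.
   Each variant's docking score ΔG becomes ΔΔG = ΔG<sup>V</sup> −
   ΔG<sup>WT</sup>; sites with ΔΔG strictly below the selection
   threshold **mean(ΔΔG) − SD(ΔΔG)** advance. Iterative ASM then
   enumerates every subset of the nominated sites
   (C(n, r) variants per size r; 255 in total for 8 sites).
3. **Site-saturation (SSM)** — 19 substitutions per site (20 rows with
   the WT) and the full 20 × 20 grid for a site pair (400 rows =
   1 WT + 38 singles + 361 doubles).
4. **Docking post-processing** — pose sets are leader-clustered at a
   2.0 Å RMSD tolerance (no superposition; poses share the receptor
   frame), cluster representatives must place a ligand heavy atom
   within 4.0 Å of the catalytic serine OG and contact every configured
   cleft subsite, and the lowest-energy accepted representative is the
   variant's ΔG.
5. **Sequence-space maps** — ΔΔG distributions by mutation count,
   fixed-site maps over the combinatorial scan, and side-chain-class
   (P1–P6) maps for saturation grids.
6. **MD / MM-PBSA post-analysis** — Kabsch-superposed RMSD series,
   per-residue RMSF over a trailing window, catalytic-distance series
   with closest-carbon tracking, hydrogen-bond geometry, equidistant
   snapshot selection, Shrake–Rupley SASA with the apolar model
   G<sub>apolar</sub> = 0.0226778·SASA + 3.84982 kJ/mol, term-wise
   binding energies ΔG = G<sub>complex</sub> − (G<sub>protein</sub> +
   G<sub>ligand</sub>) with mean ± SD summaries, and per-residue
   decomposition deltas against averaged WT replicas.

## Worked example

Run the full synthetic reverse screen (42 candidate sites, 8 planted
strong sites, Gaussian docking noise):

```sh
petscreen run-all --seed 1 --out-dir out
```

prints (abridged):

```json
{
 "asm_single_variants": 42,
 "n_negative_ddg": 17,
 "threshold_cutoff": -1.0114073507008168,
 "selected_sites": [87, 112, 119, 205, 214, 238, 253, 280],
 "asm_combinatorial_variants": 255,
 "best_mutation_count": 2,
 "best_single": "S238C",
 "best_single_ddg": -2.8068195811672183,
 "ssm_double_variants": 400,
 "best_double": "D112M/S238F",
 "best_double_ddg": -5.198145691628614
}
```

Reading this: of the 42 single-alanine variants, 17 docked better than
the WT; the mean − SD threshold (−1.01 kcal/mol) nominated exactly the
8 planted strong sites; the 255-variant combinatorial scan found its
optimum at two simultaneous substitutions; saturation then identified
S238C as the best single substitution and D112M/S238F as the best
double — the variants planted in the synthetic landscape. Per-stage
TSVs (screen records, sequence-space maps) land in `out/`.

The same stages run individually (`petscreen sites|asm|asm-iter|ssm|
screen|space|mmpbsa|simulate`) on your own alignment, pose, trajectory
or energy-table files; `petscreen simulate` writes example inputs for
each format.

As a library:

```python
from petscreen import synthetic, pipeline
landscape = synthetic.default_landscape(seed=1)
report = pipeline.run_reverse_screen(landscape)
```

## Layout

| module | contents |
| --- | --- |
| `petscreen.msa` | alignment IO, percent identity, conservation, site nomination |
| `petscreen.variants` | Variant/Library types, ASM and SSM enumeration |
| `petscreen.docking` | pose types and IO, RMSD, leader clustering, filters, ΔΔG, threshold |
| `petscreen.seqspace` | residue classes P1–P6, mutation-count / fixed-site / class maps |
| `petscreen.md` | trajectories, Kabsch superposition, RMSD/RMSF, distances, H-bonds |
| `petscreen.mmpbsa` | snapshot selection, Shrake–Rupley SASA, apolar model, binding summaries |
| `petscreen.synthetic` | landscape, pose-set, trajectory, energy-table and alignment generators |
| `petscreen.pipeline` / `petscreen.cli` | stage orchestration and the `petscreen` command |

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
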