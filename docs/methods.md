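# Methods

## The screening model

The pipeline treats enzyme improvement as a search over a
variant → binding-score map. A *variant* is a sparse set of
substitutions on the reference enzyme (the empty set is the wild type);
its score ΔG is the docking energy (kcal/mol) of the best accepted
substrate pose, and decisions are made on
ΔΔG = ΔG<sup>V</sup> − ΔG<sup>WT</sup>. The pipeline never computes
docking energies itself — they are engine outputs or synthetic — but it
owns everything around them: which sites enter the scan, how raw poses
become one ΔG, which variants advance, and how the results are
summarised.

### Site nomination

Candidate sites come from a multiple sequence alignment of the enzyme
against homologous PET hydrolases. Per-column conservation is scored by
physicochemical property counting (Livingstone & Barton 1993): ten
binary properties (hydrophobic, polar, small, proline, tiny, aliphatic,
aromatic, positive, negative, charged), one point per property whose
membership status is uniform over the column's non-gap residues, and 11
for an identical column. The original study delegated this score to an
alignment viewer's default method; we fix the property-counting variant
because it is deterministic and testable, and ship the property table as
editable YAML. On mixed columns other viewer variants can differ by
about ±1, which is why the cutoff is a parameter. Gaps are skipped;
columns with more than 50% gaps are flagged low-confidence. The
nomination rule: loop residues marked near the active site pass
unconditionally (that marking is input configuration — it comes from
inspecting the crystal structure, not from the alignment); non-loop
residues pass when conservation < 6 (strict); explicit overrides admit
sites reported by earlier mutagenesis work; catalytic-triad residues
(S160/D206/H237) never pass.

Percent identity between two rows is 100 × (identical non-gap columns) /
(columns where at least one row is non-gap) — the common viewer
convention; shared gap columns are ignored.

### Library enumeration

Alanine scanning: one Ala variant per site, then every subset of the
nominated sites (sizes r in [r_min, r_max]; C(n, r) variants each; for
n = 8 the sizes are 8/28/56/70/56/28/8/1, total 255). Saturation: all
19 non-WT standard amino acids per site, or the full 20 × 20 grid for a
pair, containing the WT exactly once (1 + 2·19 + 19² = 400). Variant
labels are canonical ("D112M/S238F": ascending position, "/"-joined)
and act as primary keys across all modules. Sites whose WT residue is
already Ala, duplicate sites and catalytic sites are rejected at input.

### From poses to ΔG

Docking engines emit hundreds of poses per variant. Reduction follows
the engine's own clustering convention: poses are visited best-energy
first and leader-clustered at a 2.0 Å RMSD tolerance, RMSD computed
without superposition because all poses share the receptor frame (no
ligand-symmetry correction; the atom order of the ligand file is
authoritative). Cluster representatives are then filtered geometrically:
the minimum distance from any ligand heavy atom to the catalytic serine
side-chain oxygen (OG) must be strictly below 4.0 Å (the minimum is the
permissive reading — the substrate atom involved is not specified), and
for each configured cleft subsite (residue sets lining the two arms of
the L-shaped binding cleft) at least one ligand atom must lie within
5.0 Å of a subsite atom. The lowest-energy accepted representative is
the variant's ΔG; equal energies break ties toward the lower pose id.
If no cluster passes, ΔG is undefined and the record carries the failure
reasons; such records are excluded from maps but counted.

### Selection threshold

Variants advance when ΔΔG lies strictly below mean(ΔΔG) − SD(ΔΔG) over
the scanned set. SD is the sample standard deviation (n − 1); the source
study says only "standard deviation", so the choice is exposed. The
rule is invariant under a common shift of all ΔG (so the WT's own noise
draw cancels) and scales linearly under positive scaling — both covered
by exhaustive randomized tests.

### Sequence-space maps

Three aggregations over screen records: per-mutation-count distribution
summaries (n/min/quartiles/mean); fixed-site maps (r × site matrix,
aggregate over all size-r variants containing the site — default
aggregator `min`, because the screening question is "does any variant
containing this site improve?"); and side-chain-class maps for
saturation grids (default `mean`, reflecting that class effects are
distributional). The classes P1–P6 are not enumerated in the source
figures, so a default partition ships as editable data — P1 small
aliphatic (G,A,V,L,I,P), P2 aromatic (F,Y,W), P3 polar uncharged
(S,T,N,Q,C,M), P4 positive (K,R,H), P5 negative (D,E), P6 reserved —
and every map records the table it used.

### MD post-processing

Internal units are Å and ps. Superposition is a Kabsch least-squares
fit (proper rotation; implemented on scipy's quaternion solver, with the
residual recomputed from the fitted coordinates because the solver's
own residual is only ~1e-7 accurate near exact fits). RMSD series
superpose each sampled frame on the reference frame (frame 0 — the
energy-minimized start — by default) over the analysis selection.
RMSF is computed per residue on Cα (residue-centroid fallback) about
the window-mean position, after superposing the window on the backbone
of the running mean (two passes); the window defaults to the trailing
half of the trajectory, generalising "last 50 ns of a 100 ns run";
absolute-time windows are supported when dt is known. Which atoms the
original analyses fitted is unstated, so both backbone and all-atom
selections are available. The catalytic-distance series reports, per
frame, the distance from the serine OG to each configured substrate
carbonyl carbon (C1–C4) plus the per-frame closest label, which is how
substrate sliding along the cleft is read. Hydrogen bonds use a standard
geometric criterion — donor–acceptor heavy distance ≤ 3.5 Å and
donor–H···acceptor angle ≥ 120° — as the source named none.

### MM/PBSA bookkeeping

Binding energy is the end-point difference ΔG = G_complex − (G_protein +
G_ligand), term-wise over vdW, electrostatic, polar-solvation and
apolar-solvation components (kJ/mol), averaged over snapshots; entropy
is omitted, matching the source protocol. The vacuum and polar terms are
*inputs* parsed from engine tables — re-implementing a force field or a
Poisson–Boltzmann solver is out of scope (the dielectric constants 4 and
80 are carried as metadata only). Only the apolar term is recomputable:
a Shrake–Rupley SASA (golden-spiral quadrature, 960 points/atom, probe
1.4 Å, Bondi element radii as editable data) in the linear model
G_apolar = 0.0226778·SASA + 3.84982 kJ/mol. Snapshots are equidistant
over the trailing half: an exact stride when the window divides evenly
(1000 frames / 500 → every 2nd), otherwise endpoint-inclusive rounding
whose gaps never differ by more than one frame. Summaries report
mean ± sample SD per Δterm and of the per-frame totals, so the total
mean equals the sum of term means exactly on unrounded values. The
"±" of the bundled reference table is taken to be SD over snapshots.
Per-residue decomposition deltas subtract the *average of the two WT
replicas' mean profiles* (not pooled snapshots); negative values are
binding-energy gains.

A published MM/PBSA summary for the WT and the Q119F, D112M/S238F and
S238C variants (two replicas each) ships as a small reference TSV; its
internal consistency — component means summing to the printed totals
within the 1 kJ/mol rounding budget, four rows exactly — is asserted in
the acceptance tests, and its WT row parameterises the energy-table
generator.

## The synthetic generators

The generators emulate input *shapes*, not physics, and that bounds what
green tests mean: they show the bookkeeping, enumeration, clustering,
thresholding and estimators are correct on data whose truth is known,
not that any real enzyme variant binds better.

* **Landscape** — ΔG(variant) = WT energy + per-site additive effects +
  pairwise epistasis + N(0, σ²) noise drawn once per variant label
  (deterministic per label, so the WT has its own draw and repeated
  queries agree). Defaults model the study scale: 42 candidate sites,
  8 strong sites (alanine effects uniform −1.6..−1.3 kcal/mol) among 34
  weak ones (0.0..0.5), noise SD 0.2 kcal/mol, WT score −7.2 kcal/mol.
  Planted winners: S238C (−2.4, best single) and D112M/S238F (best
  double via a −2.2 pairwise coupling); +1.2 antagonistic epistasis
  between alanine pairs puts the combinatorial optimum at r ≤ 2. The
  winner margins are at least three times the SD of a ΔΔG difference,
  so the planted structure is identifiable by construction; real
  screens offer no such guarantee, which is exactly why their outcome
  needs MD-level validation.
* **Pose sets** — a rigid ligand template jittered around k centers
  10 Å apart with member–center RMSD strictly below the requested
  spread, so leader clustering at 2.0 Å provably recovers the planted
  partition; a minimal receptor (catalytic OG probe plus two subsite
  arms) supports filter tests.
* **Trajectories** — a Cα helix with independent N(0, σᵢ²) noise per
  coordinate and optional rigid drift; the planted per-residue RMSF is
  σᵢ√3. The RMSF recovery benchmark reads the fluctuations without a
  rigid-body fit because the generated frames share the lab frame and
  no rigid motion is planted; with superposition enabled, the fit
  itself injects lever-arm noise from high-σ residues into low-σ ones
  (up to ~20% on this elongated chain), which is a real property of
  superposed RMSF, not an estimator defect. Drift-removal correctness
  is tested separately.
* **Energy tables** — Gaussian Δ-term draws on fixed protein/ligand
  baselines, so the summaries recover the parameters exactly in the
  zero-SD limit; the optional per-residue split (Dirichlet weights)
  sums to each frame's total by construction.

All randomness fans out from one seed through
`SeedSequence([seed, crc32(tag)])` child streams; equal seeds give
byte-identical outputs.

## Problem sizes and defaults

The bundled benchmarks use 200 random pose sets (≤ 8 poses) for the
clustering oracle, 50 random 10-atom cases for the Kabsch-vs-grid
bound, 50 residues × 10⁴ frames for RMSF recovery, 500 snapshots for
energy summaries and 10³ random vectors for the threshold invariance
suite — sizes at which the statistical tolerances (5% RMSF, 1–2% SASA,
3σ/√n means) are comfortably resolved on a single CPU in seconds.

## Known limitations

* Conservation scores can differ by ±1 from other viewer variants on
  mixed columns; the <6 gate is therefore configurable.
* Pose RMSD has no ligand-symmetry correction; symmetric substrates
  will over-estimate RMSD between mirror-equivalent poses.
* The subsite definitions of the L-shaped cleft are configuration, not
  derived from structure; defaults are schematic.
* The published 44.93% identity against TfCut2 depends on the
  externally distributed crystal-structure sequences and a progressive
  aligner; the package verifies the identity *definition* on generated
  families instead and computes the published figure only when those
  sequences are supplied.
* Real docking/MD observables (absolute ΔG values, "11 of 42" negative
  counts, trajectory traces) are engine-dependent and are not
  reproduced — the pipeline reproduces the decision logic around them.
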