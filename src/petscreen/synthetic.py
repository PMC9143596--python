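"""Synthetic inputs with planted ground truth for every pipeline stage.

Nothing here aspires to physical realism: the generators emulate the
*shapes* of the real inputs — a variant -> docking-energy landscape with
per-site additive effects, pairwise epistasis and Gaussian noise; pose
sets with known cluster structure; trajectories with known per-residue
fluctuation amplitudes; per-frame MM/PBSA component tables with known
means and SDs — so that every screening and analysis stage can be tested
against a known answer, without docking or MD engines.

All randomness flows from one integer seed: each generator derives a
child generator from ``SeedSequence([seed, crc32(tag)])``, so the same
seed gives byte-identical outputs and different components never share a
stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .docking import Pose
from .md import Trajectory
from .mmpbsa import ENTITIES, TERMS, EnergyFrame
from .msa import AlignedSet
from .variants import STANDARD_AA, Variant

CATALYTIC_TRIAD = (160, 206, 237)


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-component generator derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    )


# ---------------------------------------------------------------------------
# Binding-energy landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Variant -> docking-score landscape specification (kcal/mol).

    ``additive[(site, aa)]`` is the effect of placing ``aa`` at ``site``
    (WT identity has effect 0 by construction and must not appear);
    ``epistasis[((site_a, aa_a), (site_b, aa_b))]`` adds a pairwise
    term when both substitutions are present.  Gaussian noise of SD
    ``noise_sd`` is drawn once per variant label (the WT draws its own),
    so repeated queries are reproducible.
    """

    sites: list[int]
    wt_residues: dict[int, str]
    wt_energy: float = -7.2
    additive: dict[tuple[int, str], float] = field(default_factory=dict)
    epistasis: dict[tuple[tuple[int, str], tuple[int, str]], float] = field(
        default_factory=dict
    )
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for (site, aa) in self.additive:
            if self.wt_residues.get(site) == aa:
                raise ValueError(
                    f"additive effect on WT identity {aa}{site} must be absent"
                )


class Landscape:
    """Deterministic scorer over variants, with planted ground truth."""

    def __init__(self, cfg: LandscapeConfig):
        self.cfg = cfg
        self._epi = {}
        for (a, b), v in cfg.epistasis.items():
            key = tuple(sorted((a, b)))
            self._epi[key] = v

    @property
    def sites(self) -> list[int]:
        return list(self.cfg.sites)

    @property
    def wt_residues(self) -> dict[int, str]:
        return dict(self.cfg.wt_residues)

    def _noise(self, label: str) -> float:
        if self.cfg.noise_sd == 0:
            return 0.0
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(self.cfg.seed), zlib.crc32(label.encode())]
            )
        )
        return float(rng.normal(0.0, self.cfg.noise_sd))

    def delta_g(self, variant: Variant) -> float:
        """Docking score of a variant (kcal/mol), noise included."""
        total = self.cfg.wt_energy
        subs = []
        for pos, _wt, new in variant.substitutions:
            if pos not in self.cfg.wt_residues:
                raise KeyError(f"unknown site {pos} in variant {variant.label}")
            subs.append((pos, new))
            total += self.cfg.additive.get((pos, new), 0.0)
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                key = tuple(sorted((subs[i], subs[j])))
                total += self._epi.get(key, 0.0)
        return total + self._noise(variant.label)

    def delta_delta_g(self, variant: Variant) -> float:
        return self.delta_g(variant) - self.delta_g(Variant())

    def noiseless(self) -> "Landscape":
        return Landscape(replace(self.cfg, noise_sd=0.0))

    def true_best(self, library) -> str:
        """Label of the library variant with the lowest noise-free score."""
        clean = self.noiseless()
        return min(library, key=lambda v: (clean.delta_g(v), v.label)).label


#: Default planted structure: candidate scan sites, strong sites and winners.
STRONG_SITES = {87: "Y", 112: "D", 119: "Q", 205: "N", 214: "S", 238: "S",
                253: "K", 280: "R"}
DOUBLE_SSM_SITES = (112, 238)


def default_landscape(seed: int = 0, noise_sd: float = 0.2) -> Landscape:
    """The study-scale landscape: 42 candidate sites, 8 planted strong sites.

    Alanine effects: strong sites uniform in (−1.6, −1.3) kcal/mol, the
    34 weak sites uniform in (0.0, 0.5); the selection threshold
    mean − SD then separates the two groups.  Saturation effects at the
    strong sites are class-structured with planted winners S238C (best
    single, −2.4) and — through a favourable pairwise coupling —
    D112M/S238F (best double on the 112 x 238 grid).  Antagonistic
    alanine-pair epistasis (+1.2 per pair) makes the combinatorial-scan
    optimum occur at r <= 2.
    """
    rng = child_rng(seed, "landscape")
    strong = dict(STRONG_SITES)
    weak_pool = [
        r
        for r in range(58, 300, 6)
        if r not in strong and r not in CATALYTIC_TRIAD
    ]
    weak_sites = weak_pool[:34]
    wt_residues = dict(strong)
    non_ala = [aa for aa in STANDARD_AA if aa != "A"]
    for s in weak_sites:
        wt_residues[s] = non_ala[int(rng.integers(len(non_ala)))]

    additive: dict[tuple[int, str], float] = {}
    for s in strong:
        additive[(s, "A")] = float(rng.uniform(-1.6, -1.3))
    for s in weak_sites:
        additive[(s, "A")] = float(rng.uniform(0.0, 0.5))

    # Class-structured saturation effects at the strong sites.
    from .seqspace import classify_residue, load_residue_classes

    class_table = load_residue_classes()
    for s, wt in strong.items():
        base = {
            cid: float(rng.normal(0.0, 0.4)) for cid in class_table
        }
        for aa in STANDARD_AA:
            if aa == wt or aa == "A":
                continue
            eff = base[classify_residue(aa, class_table)] + float(
                rng.normal(0.0, 0.15)
            )
            additive[(s, aa)] = float(np.clip(eff, -1.0, 0.8))
    # Planted winners (all other saturation effects are clipped >= -1.0).
    # The margin between the best single (S238C) and the runner-up (Q119F)
    # is 0.6 kcal/mol, three times the SD of a ΔΔG difference at the
    # default noise level, so the winner is identifiable by construction.
    additive[(238, "C")] = -2.4
    additive[(238, "F")] = -1.6
    additive[(119, "F")] = -1.8
    additive[(112, "M")] = -1.2

    epistasis: dict[tuple[tuple[int, str], tuple[int, str]], float] = {}
    strong_list = sorted(strong)
    for i in range(len(strong_list)):
        for j in range(i + 1, len(strong_list)):
            a, b = strong_list[i], strong_list[j]
            epistasis[((a, "A"), (b, "A"))] = 1.2
    epistasis[((112, "M"), (238, "F"))] = -2.2

    cfg = LandscapeConfig(
        sites=sorted(wt_residues),
        wt_residues=wt_residues,
        wt_energy=-7.2,
        additive=additive,
        epistasis=epistasis,
        noise_sd=noise_sd,
        seed=seed,
    )
    return Landscape(cfg)


# ---------------------------------------------------------------------------
# Docking pose sets
# ---------------------------------------------------------------------------

def gen_pose_set(
    k_clusters: int,
    spread: float,
    n_poses: int,
    energies: Sequence[float] | None = None,
    seed: int = 0,
    n_atoms: int = 12,
    center_sep: float = 10.0,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    variant_label: str = "WT",
) -> tuple[list[Pose], np.ndarray, np.ndarray]:
    """Poses jittered around k well-separated centers.

    Returns ``(poses, true_labels, centers)``; every pose's RMSD to its
    center is strictly below ``spread``, and centers are ``center_sep``
    apart, so leader clustering at any tolerance in
    (2*spread, center_sep − 2*spread) recovers the planted partition.
    """
    if spread >= center_sep / 2:
        raise ValueError("spread must be < center_sep / 2")
    if k_clusters < 1 or n_poses < k_clusters:
        raise ValueError("need n_poses >= k_clusters >= 1")
    rng = child_rng(seed, "poses")
    template = rng.uniform(-1.5, 1.5, size=(n_atoms, 3))
    centers = np.asarray(origin, dtype=float) + np.stack(
        [np.array([i * center_sep, 0.0, 0.0]) for i in range(k_clusters)]
    )
    # Round-robin assignment guarantees every cluster is populated.
    labels = np.array([i % k_clusters for i in range(n_poses)])
    if energies is None:
        energies = rng.uniform(-8.0, -4.0, size=n_poses)
    energies = np.asarray(energies, dtype=float)
    if energies.shape != (n_poses,):
        raise ValueError("energies must have one value per pose")
    poses = []
    for pid in range(n_poses):
        base = centers[labels[pid]] + template
        while True:
            jitter = rng.normal(0.0, spread / (2 * np.sqrt(3)), size=(n_atoms, 3))
            rmsd = np.sqrt(np.mean(np.sum(jitter**2, axis=1)))
            if rmsd < spread:
                break
        poses.append(
            Pose(
                pose_id=pid,
                coords=base + jitter,
                energy=float(energies[pid]),
                variant_label=variant_label,
            )
        )
    return poses, labels, centers + template.mean(axis=0)


def gen_receptor(
    catalytic_xyz: Sequence[float] = (0.0, 0.0, 0.0),
    subsite_atoms: Mapping[str, Mapping[int, Sequence[float]]] | None = None,
) -> pd.DataFrame:
    """Minimal receptor atom table: a catalytic serine OG plus cleft subsites.

    ``subsite_atoms`` maps subsite name -> {residue number: xyz}; the
    default places subsite I at x=+6 and subsite II at z=+6 around the
    catalytic probe, sketching an L-shaped cleft.
    """
    cx, cy, cz = catalytic_xyz
    if subsite_atoms is None:
        subsite_atoms = {
            "I": {87: (cx + 6.0, cy, cz), 119: (cx + 9.0, cy, cz)},
            "II": {238: (cx, cy, cz + 6.0), 280: (cx, cy, cz + 9.0)},
        }
    rows = [
        dict(name="OG", resname="SER", chain="A", resid=160, element="O",
             x=cx, y=cy, z=cz)
    ]
    for atoms in subsite_atoms.values():
        for resid, (x, y, z) in atoms.items():
            rows.append(
                dict(name="CB", resname="UNK", chain="A", resid=int(resid),
                     element="C", x=float(x), y=float(y), z=float(z))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryConfig:
    """Per-residue isotropic-Gaussian fluctuation model for a Cα chain."""

    n_residues: int
    n_frames: int
    dt: float = 10.0  # ps
    sigma: float | Sequence[float] = 0.3  # Å per coordinate, scalar or per residue
    drift: Sequence[float] | None = None  # Å per frame rigid translation
    seed: int = 0

    def sigma_array(self) -> np.ndarray:
        sig = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), (self.n_residues,)
        ).copy()
        if np.any(sig < 0):
            raise ValueError("sigma must be >= 0")
        return sig


def gen_trajectory(cfg: TrajectoryConfig) -> tuple[Trajectory, np.ndarray]:
    """A Cα-chain trajectory with planted per-residue fluctuation amplitudes.

    Base coordinates trace a coarse helix (3.8 Å rise); each frame adds
    independent N(0, σᵢ²) noise per coordinate of residue i, plus an
    optional rigid per-frame drift.  Returns the trajectory and the true
    σᵢ (the per-residue RMSF about the mean is σᵢ·√3).
    """
    sig = cfg.sigma_array()
    rng = child_rng(cfg.seed, "trajectory")
    t = np.arange(cfg.n_residues)
    base = np.column_stack(
        [6.0 * np.cos(t * 0.6), 6.0 * np.sin(t * 0.6), 3.8 * t]
    )
    noise = rng.normal(size=(cfg.n_frames, cfg.n_residues, 3)) * sig[None, :, None]
    frames = base[None] + noise
    if cfg.drift is not None:
        drift = np.asarray(cfg.drift, dtype=float)
        frames = frames + drift[None, None, :] * np.arange(cfg.n_frames)[
            :, None, None
        ]
    topology = pd.DataFrame(
        {
            "name": ["CA"] * cfg.n_residues,
            "resid": np.arange(1, cfg.n_residues + 1),
            "resname": ["ALA"] * cfg.n_residues,
            "chain": ["A"] * cfg.n_residues,
            "element": ["C"] * cfg.n_residues,
        }
    )
    return Trajectory(topology=topology, frames=frames, dt=cfg.dt), sig


# ---------------------------------------------------------------------------
# MM/PBSA component tables
# ---------------------------------------------------------------------------

def gen_energy_frames(
    delta_means: Mapping[str, float],
    delta_sds: Mapping[str, float],
    n: int = 500,
    seed: int = 0,
    residues: Sequence[int] | None = None,
) -> list[EnergyFrame]:
    """Gaussian per-frame MM/PBSA tables with known Δ-term means/SDs (kJ/mol).

    The Δ (binding) terms are drawn N(mean, sd) per frame; fixed
    protein/ligand baselines are added so the per-entity tables look
    like engine output while ``binding_energy`` recovers exactly the
    drawn Δs.  With ``residues`` given, each frame carries a per-residue
    decomposition (Dirichlet split) that sums to that frame's total.
    """
    if n < 2:
        raise ValueError("need n >= 2 frames")
    for t in TERMS:
        if t not in delta_means or t not in delta_sds:
            raise ValueError(f"missing Δ parameters for term {t!r}")
        if delta_sds[t] < 0:
            raise ValueError(f"negative SD for term {t!r}")
    rng = child_rng(seed, "energy")
    baselines = {
        "protein": {"vdw": -900.0, "electrostatic": -4200.0, "polar": 1500.0,
                    "apolar": 110.0},
        "ligand": {"vdw": -40.0, "electrostatic": -120.0, "polar": 90.0,
                   "apolar": 12.0},
    }
    frames = []
    for i in range(n):
        deltas = {
            t: float(rng.normal(delta_means[t], delta_sds[t])) for t in TERMS
        }
        terms = {e: dict(baselines[e]) for e in ("protein", "ligand")}
        terms["complex"] = {
            t: baselines["protein"][t] + baselines["ligand"][t] + deltas[t]
            for t in TERMS
        }
        per_residue = None
        if residues is not None:
            w = rng.dirichlet(np.ones(len(residues)))
            total = sum(deltas.values())
            per_residue = {
                int(r): float(wi * total) for r, wi in zip(residues, w)
            }
        frames.append(
            EnergyFrame(frame_index=i, terms=terms, per_residue=per_residue)
        )
    return frames


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def gen_alignment(
    seed: int = 0,
    ref_id: str = "REF",
    homolog_identity: Sequence[float] = (0.45, 0.41, 0.44),
    length: int = 120,
    gap_frac: float = 0.03,
) -> AlignedSet:
    """A synthetic homolog family at controlled per-column identity levels.

    The (gapless) reference row is random; each homolog keeps the
    reference residue with its target probability, substitutes a
    different residue otherwise, and converts a small fraction of
    columns to gaps.
    """
    rng = child_rng(seed, "alignment")
    aas = list(STANDARD_AA)
    ref = "".join(rng.choice(aas, size=length))
    ids, rows = [ref_id], [ref]
    for h, ident in enumerate(homolog_identity):
        seq = []
        for c in ref:
            if rng.random() < ident:
                seq.append(c)
            else:
                choices = [a for a in aas if a != c]
                seq.append(choices[int(rng.integers(len(choices)))])
        for pos in np.flatnonzero(rng.random(length) < gap_frac):
            seq[pos] = "-"
        ids.append(f"HOM{h + 1}")
        rows.append("".join(seq))
    return AlignedSet(ids=ids, rows=rows, ref_id=ref_id)
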