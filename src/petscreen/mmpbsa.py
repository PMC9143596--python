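"""MM/PBSA bookkeeping: snapshot selection, SASA-based apolar solvation,
binding-energy totals and per-residue decomposition deltas.

The binding free energy is the end-point difference
``ΔG_binding = G_complex − (G_protein + G_ligand)`` taken term-wise over
van der Waals, electrostatic, polar-solvation and apolar-solvation
components (kJ/mol), averaged over equidistant snapshots from the
equilibrated tail of a trajectory.  Entropy is omitted.  The vacuum and
polar terms are engine outputs parsed from tables; only the apolar term
is recomputed internally, from a Shrake–Rupley solvent-accessible
surface area with the linear model

    G_apolar = 0.0226778 kJ/(mol·Å²) · SASA + 3.84982 kJ/mol.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

ENTITIES = ("complex", "protein", "ligand")
TERMS = ("vdw", "electrostatic", "polar", "apolar")

#: Surface tension of the solvent, kJ/(mol Å^2).
APOLAR_GAMMA = 0.0226778
#: SASA energy constant (offset), kJ/mol.
APOLAR_CONST = 3.84982


@dataclass
class EnergyFrame:
    """Per-snapshot MM/PBSA components for complex/protein/ligand (kJ/mol).

    ``terms[entity][term]`` holds the four components; ``per_residue``
    optionally carries a per-residue decomposition of the binding energy
    that sums to this frame's total.
    """

    frame_index: int
    terms: dict[str, dict[str, float]]
    per_residue: dict[int, float] | None = None

    def __post_init__(self) -> None:
        for entity in ENTITIES:
            if entity not in self.terms:
                raise ValueError(f"missing component record for {entity!r}")
            for term in TERMS:
                v = self.terms[entity].get(term)
                if v is None or not np.isfinite(v):
                    raise ValueError(f"{entity}.{term} missing or non-finite")


@dataclass
class BindingSummary:
    """Mean ± sample SD of each Δterm and of the per-frame totals."""

    term_mean: dict[str, float]
    term_sd: dict[str, float]
    total_mean: float
    total_sd: float
    n_snapshots: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "mean": self.term_mean[t], "sd": self.term_sd[t]}
            for t in TERMS
        ]
        rows.append({"term": "total", "mean": self.total_mean, "sd": self.total_sd})
        df = pd.DataFrame(rows)
        df["n"] = self.n_snapshots
        return df


def select_snapshots(
    n_frames: int, n_select: int = 500, window="last_half"
) -> np.ndarray:
    """Equidistant snapshot indices spanning the window, endpoints included.

    ``window`` is "last_half" or an explicit (start, end) frame range
    (end exclusive).  If the window holds fewer than ``n_select`` frames
    every frame is taken, with a warning.
    """
    if window == "last_half":
        start, end = n_frames // 2, n_frames
    else:
        start, end = window
    if not (0 <= start < end <= n_frames):
        raise ValueError(f"empty or invalid window ({start}, {end})")
    size = end - start
    if size < n_select:
        warnings.warn(
            f"window holds {size} < n_select={n_select} frames; taking all"
        )
        return np.arange(start, end)
    if n_select == 1:
        return np.array([start])
    if size % n_select == 0:
        # exact stride (e.g. every 2nd frame of a 1000-frame window)
        return np.arange(start, end, size // n_select)
    idx = np.rint(np.linspace(start, end - 1, n_select)).astype(int)
    return np.unique(idx)


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def load_radii_table(path=None) -> dict[str, float]:
    src = (
        path
        if path is not None
        else importlib.resources.files("petscreen.data").joinpath("vdw_radii.yaml")
    )
    with open(src) as fh:
        return {str(k).upper(): float(v) for k, v in yaml.safe_load(fh).items()}


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å².

    For each atom, test points on its probe-expanded sphere (radius
    r_i + probe) are kept if they fall inside no neighbour's expanded
    sphere; the accessible fraction times the expanded-sphere area is
    that atom's SASA.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    if radii.shape != (coords.shape[0],):
        raise ValueError("radii must be per-atom")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("radii must be positive and finite")
    n = coords.shape[0]
    expanded = radii + probe
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_reach = 2 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j]
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def sasa(
    structure: pd.DataFrame,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    radii_table: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, float]:
    """SASA of an atom table (needs element + x/y/z columns): per-atom and total."""
    if radii_table is None:
        radii_table = load_radii_table()
    elements = structure["element"].astype(str).str.upper()
    missing = sorted(set(elements) - set(radii_table))
    if missing:
        raise KeyError(f"no vdW radius for elements: {missing}")
    radii = elements.map(radii_table).to_numpy(dtype=float)
    coords = structure[["x", "y", "z"]].to_numpy(dtype=float)
    per_atom = shrake_rupley(coords, radii, probe, n_sphere_points)
    return per_atom, float(per_atom.sum())


def apolar_energy(
    sasa_total: float, gamma: float = APOLAR_GAMMA, const: float = APOLAR_CONST
) -> float:
    """Linear SASA model for the non-polar solvation term (kJ/mol)."""
    if sasa_total < 0:
        raise ValueError("SASA cannot be negative")
    return gamma * sasa_total + const


# ---------------------------------------------------------------------------
# Binding-energy bookkeeping
# ---------------------------------------------------------------------------

def binding_energy(frame: EnergyFrame) -> dict[str, float]:
    """Term-wise Δ = complex − (protein + ligand), plus their sum as 'total'."""
    out: dict[str, float] = {}
    for term in TERMS:
        out[term] = frame.terms["complex"][term] - (
            frame.terms["protein"][term] + frame.terms["ligand"][term]
        )
    out["total"] = float(sum(out[t] for t in TERMS))
    return out


def summarize(frames: Sequence[EnergyFrame]) -> BindingSummary:
    """Mean and sample SD of each Δterm and the per-frame totals."""
    if len(frames) < 2:
        raise ValueError("summary needs at least 2 frames")
    deltas = pd.DataFrame([binding_energy(f) for f in frames])
    return BindingSummary(
        term_mean={t: float(deltas[t].mean()) for t in TERMS},
        term_sd={t: float(deltas[t].std(ddof=1)) for t in TERMS},
        total_mean=float(deltas["total"].mean()),
        total_sd=float(deltas["total"].std(ddof=1)),
        n_snapshots=len(frames),
    )


def mean_residue_profile(frames: Sequence[EnergyFrame]) -> pd.Series:
    """Mean per-residue binding-energy contribution over snapshots."""
    profiles = [f.per_residue for f in frames]
    if any(p is None for p in profiles):
        raise ValueError("frames lack per-residue decomposition")
    keys = set(profiles[0])
    for p in profiles[1:]:
        if set(p) != keys:
            raise ValueError("per-residue keys differ between frames")
    df = pd.DataFrame(profiles)
    return df.mean(axis=0).sort_index()


def per_residue_delta(
    variant_frames: Sequence[EnergyFrame],
    wt_replica_frames: Sequence[Sequence[EnergyFrame]],
) -> pd.Series:
    """Per-residue Δ(ΔG) of a variant relative to the averaged WT replicas.

    The WT reference is the average of each replica's mean profile (not
    the pooled snapshots).  Negative values are binding-energy gains,
    positive values losses.  A residue-set mismatch raises, naming the
    offending residues.
    """
    var_profile = mean_residue_profile(variant_frames)
    wt_profiles = [mean_residue_profile(rep) for rep in wt_replica_frames]
    wt_ref = pd.concat(wt_profiles, axis=1).mean(axis=1)
    mismatch = set(var_profile.index) ^ set(wt_ref.index)
    if mismatch:
        raise ValueError(f"residue sets differ at: {sorted(mismatch)}")
    return (var_profile - wt_ref).sort_index()


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def frames_to_tsv(frames: Sequence[EnergyFrame], path,
                  residue_path=None) -> None:
    rows = []
    for f in frames:
        for entity in ENTITIES:
            rows.append(
                {"frame": f.frame_index, "entity": entity,
                 **{t: f.terms[entity][t] for t in TERMS}}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if residue_path is not None:
        res_rows = [
            {"frame": f.frame_index, "residue": res, "energy": e}
            for f in frames
            if f.per_residue
            for res, e in f.per_residue.items()
        ]
        pd.DataFrame(res_rows).to_csv(residue_path, sep="\t", index=False)


def frames_from_tsv(path, residue_path=None) -> list[EnergyFrame]:
    df = pd.read_csv(path, sep="\t")
    res_map: dict[int, dict[int, float]] = {}
    if residue_path is not None:
        rdf = pd.read_csv(residue_path, sep="\t")
        for frame, grp in rdf.groupby("frame"):
            res_map[int(frame)] = dict(
                zip(grp["residue"].astype(int), grp["energy"].astype(float))
            )
    frames = []
    for frame, grp in df.groupby("frame"):
        terms = {
            str(row["entity"]): {t: float(row[t]) for t in TERMS}
            for _, row in grp.iterrows()
        }
        frames.append(
            EnergyFrame(
                frame_index=int(frame),
                terms=terms,
                per_residue=res_map.get(int(frame)),
            )
        )
    return frames


def load_reference_binding_table() -> pd.DataFrame:
    """Bundled published MM/PBSA summary (kJ/mol) for the WT and the
    Q119F / D112M/S238F / S238C variants, two MD replicas each: per-term
    mean ± SD and the total.  Used as reference input for consistency
    checks and as realistic generator parameters."""
    src = importlib.resources.files("petscreen.data").joinpath(
        "mmpbsa_reference.tsv"
    )
    with importlib.resources.as_file(src) as p:
        return pd.read_csv(p, sep="\t")
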