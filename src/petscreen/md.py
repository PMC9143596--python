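"""Trajectory post-processing: superposition RMSD, per-residue RMSF,
catalytic-distance series and hydrogen-bond geometry.

Internal units are Å and ps.  Trajectories are ordered coordinate frames
over a fixed atom topology; multi-model PDB is the on-disk format (an
adapter to binary formats only needs to fill the same dataclass).
Rigid-body motion is removed with a Kabsch least-squares superposition
before RMSD/RMSF are reported, mirroring the convention of analysing
only internal motions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class Trajectory:
    """Frames (T, N, 3) in Å over a fixed topology table; dt in ps."""

    topology: pd.DataFrame  # columns: name, resid, resname, chain, element
    frames: np.ndarray
    dt: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (T, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError("frame atom count does not match topology")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def select(
        self,
        name: str | Sequence[str] | None = None,
        resid: int | Sequence[int] | None = None,
        resname: str | Sequence[str] | None = None,
        element: str | Sequence[str] | None = None,
        backbone: bool = False,
        calpha: bool = False,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria (AND semantics)."""
        mask = np.ones(len(self.topology), dtype=bool)

        def _match(col, value):
            values = [value] if isinstance(value, (str, int, np.integer)) else list(value)
            return self.topology[col].isin(values).to_numpy()

        if name is not None:
            mask &= _match("name", name)
        if resid is not None:
            mask &= _match("resid", resid)
        if resname is not None:
            mask &= _match("resname", resname)
        if element is not None:
            mask &= _match("element", element)
        if backbone:
            mask &= self.topology["name"].isin(BACKBONE_NAMES).to_numpy()
        if calpha:
            mask &= (self.topology["name"] == "CA").to_numpy()
        return np.flatnonzero(mask)

    def select_one(self, **criteria) -> int:
        idx = self.select(**criteria)
        if len(idx) != 1:
            raise ValueError(
                f"selection {criteria} matched {len(idx)} atoms, expected 1"
            )
        return int(idx[0])

    # -- multi-model PDB round trip (biotite-backed) -----------------------

    def to_pdb(self, path) -> None:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        n = self.n_atoms
        arr = struc.AtomArrayStack(self.n_frames, n)
        arr.coord = self.frames
        arr.atom_name = self.topology["name"].to_numpy(dtype="U6")
        arr.res_id = self.topology["resid"].to_numpy(dtype=int)
        arr.res_name = self.topology["resname"].to_numpy(dtype="U5")
        arr.chain_id = self.topology["chain"].to_numpy(dtype="U4")
        arr.element = self.topology["element"].to_numpy(dtype="U2")
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))

    @classmethod
    def from_pdb(cls, path, dt: float = 10.0) -> "Trajectory":
        import biotite.structure.io.pdb as pdb

        stack = pdb.PDBFile.read(str(path)).get_structure(model=None)
        topology = pd.DataFrame(
            {
                "name": stack.atom_name,
                "resid": stack.res_id,
                "resname": stack.res_name,
                "chain": stack.chain_id,
                "element": stack.element,
            }
        )
        return cls(topology=topology, frames=stack.coord, dt=dt)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with
    ``x_fit = rotation @ x_mobile + translation`` and the post-fit RMSD.
    The rotation is proper (det = +1).  Requires >= 3 non-collinear
    points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("invalid weights")
    cm_mob = np.average(mobile, axis=0, weights=w)
    cm_ref = np.average(reference, axis=0, weights=w)
    mob_c = mobile - cm_mob
    ref_c = reference - cm_ref
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear or coincident) atom set")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    R = rot.as_matrix()
    t = cm_ref - R @ cm_mob
    # recompute the residual from the fitted coordinates: scipy's rssd is
    # accurate only to ~1e-7 near an exact fit
    resid = mob_c @ R.T - ref_c
    rmsd = float(np.sqrt(np.sum(w * np.sum(resid**2, axis=1)) / w.sum()))
    return R, t, rmsd


def _superpose_frames(
    frames: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto ``reference`` using the fit-group atoms."""
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        R, t, _ = kabsch_superpose(frame[fit_idx], reference[fit_idx])
        out[i] = frame @ R.T + t
    return out


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: np.ndarray | Mapping | None = None,
    stride: int = 1,
    superpose: bool = True,
) -> pd.DataFrame:
    """Post-superposition RMSD of every ``stride``-th frame vs a reference frame.

    Superposition and reporting both use ``selection`` (default: all
    atoms).  Returns a DataFrame with time_ps and rmsd columns; the
    first value at stride 1 with frame-0 reference is 0.
    """
    if isinstance(selection, Mapping):
        sel = traj.select(**selection)
    elif selection is None:
        sel = np.arange(traj.n_atoms)
    else:
        sel = np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    if stride >= traj.n_frames:
        warnings.warn(
            f"stride {stride} >= n_frames {traj.n_frames}: single-point series"
        )
    ref = traj.frames[reference_frame][sel]
    idx = np.arange(0, traj.n_frames, stride)
    values = []
    for i in idx:
        mob = traj.frames[i][sel]
        if superpose:
            _, _, r = kabsch_superpose(mob, ref)
        else:
            r = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
        values.append(r)
    return pd.DataFrame({"frame": idx, "time_ps": idx * traj.dt, "rmsd": values})


def _resolve_window(traj: Trajectory, window) -> np.ndarray:
    """Frame indices for a window spec: 'last_half', int (last n), (start, end)
    frame slice, or ('time_ps', t0, t1)."""
    T = traj.n_frames
    if window == "last_half":
        return np.arange(T // 2, T)
    if isinstance(window, int):
        return np.arange(max(T - window, 0), T)
    if isinstance(window, tuple) and window and window[0] == "time_ps":
        _, t0, t1 = window
        idx = np.flatnonzero(
            (np.arange(T) * traj.dt >= t0) & (np.arange(T) * traj.dt <= t1)
        )
        return idx
    if isinstance(window, tuple) and len(window) == 2:
        return np.arange(window[0], window[1])
    raise ValueError(f"unrecognised window spec {window!r}")


def rmsf_per_residue(
    traj: Trajectory,
    window="last_half",
    superpose: bool = True,
    mode: str = "calpha",
) -> pd.Series:
    """Per-residue RMS fluctuation about the window-mean position (Å).

    Frames in the window are superposed (on backbone atoms when present,
    else all atoms) onto the window-mean structure — first pass against
    the initial window frame, second against the resulting mean — then
    the RMSF of each residue's Cα (``mode="calpha"``, falling back to the
    residue centroid when a residue has no Cα) or residue centroid
    (``mode="centroid"``) is taken over the window.
    """
    idx = _resolve_window(traj, window)
    if idx.size < 2:
        raise ValueError("RMSF window must contain at least 2 frames")
    frames = traj.frames[idx]
    if superpose:
        fit_idx = traj.select(backbone=True)
        if fit_idx.size < 3:
            fit_idx = np.arange(traj.n_atoms)
        frames = _superpose_frames(frames, frames[0], fit_idx)
        frames = _superpose_frames(frames, frames.mean(axis=0), fit_idx)

    resids = traj.topology["resid"].to_numpy()
    out: dict[int, float] = {}
    for resid in pd.unique(resids):
        atom_idx = np.flatnonzero(resids == resid)
        if mode == "calpha":
            ca = atom_idx[traj.topology["name"].to_numpy()[atom_idx] == "CA"]
            coords = frames[:, ca[0]] if ca.size else frames[:, atom_idx].mean(axis=1)
        elif mode == "centroid":
            coords = frames[:, atom_idx].mean(axis=1)
        else:
            raise ValueError(f"unknown RMSF mode {mode!r}")
        mean_pos = coords.mean(axis=0)
        out[int(resid)] = float(
            np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=1)))
        )
    return pd.Series(out, name="rmsf")


def distance_series(
    traj: Trajectory,
    atom_a: Mapping,
    atoms_b: Mapping,
) -> pd.DataFrame:
    """Per-frame distances from one probe atom to each atom of a target set.

    ``atom_a`` must resolve to exactly one atom (e.g. the catalytic
    serine OG); ``atoms_b`` to >= 1 atoms (e.g. the substrate carbonyl
    carbons C1–C4).  The returned frame has one distance column per
    target atom plus ``closest`` (per-frame argmin label), which tracks
    substrate sliding along the cleft.
    """
    ia = traj.select_one(**atom_a)
    ib = traj.select(**atoms_b)
    if ib.size == 0:
        raise ValueError("atoms_b selects no atoms")
    labels = [
        f"{traj.topology['name'].iloc[i]}_{traj.topology['resid'].iloc[i]}"
        for i in ib
    ]
    d = np.linalg.norm(traj.frames[:, ib] - traj.frames[:, [ia]], axis=2)
    df = pd.DataFrame(d, columns=labels)
    df.insert(0, "time_ps", np.arange(traj.n_frames) * traj.dt)
    df["closest"] = [labels[j] for j in np.argmin(d, axis=1)]
    return df


def hydrogen_bonds(
    coords: np.ndarray,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
) -> list[dict]:
    """Geometric hydrogen bonds in one frame.

    ``donors`` are (heavy-atom index, attached-H index) pairs; a bond is
    reported when the donor-heavy to acceptor distance is <= ``d_cut`` Å
    and the donor–H···acceptor angle is >= ``angle_cut`` degrees.
    """
    coords = np.asarray(coords, dtype=float)
    out = []
    for d_idx, h_idx in donors:
        if d_idx == h_idx:
            raise ValueError("donor heavy atom and hydrogen must differ")
        d_xyz, h_xyz = coords[d_idx], coords[h_idx]
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            a_xyz = coords[a_idx]
            dist = float(np.linalg.norm(a_xyz - d_xyz))
            if dist > d_cut:
                continue
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            angle = float(
                np.degrees(np.arccos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)))
            )
            if angle >= angle_cut:
                out.append(
                    {
                        "donor": int(d_idx),
                        "hydrogen": int(h_idx),
                        "acceptor": int(a_idx),
                        "distance": dist,
                        "angle": angle,
                    }
                )
    return out
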