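"""Docking-pose clustering, geometric acceptance filtering and ΔΔG selection.

Raw docking output (hundreds of independent runs per variant) is reduced
to a single binding score per variant:

1. poses are leader-clustered at an RMSD tolerance (default 2.0 Å,
   computed without superposition since all poses share the receptor
   frame);
2. cluster representatives must place the substrate productively — a
   ligand heavy atom within 4.0 Å of the catalytic serine side-chain
   oxygen (OG) and contacts with every configured cleft subsite;
3. the lowest-energy accepted representative is the variant's ΔG, and
   ΔΔG = ΔG(variant) − ΔG(WT).

Variants with ΔΔG strictly below the selection threshold
mean(ΔΔG) − SD(ΔΔG) are nominated for the next screening round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class Pose:
    """One docking pose: ligand heavy-atom coordinates plus engine energy."""

    pose_id: int
    coords: np.ndarray  # (N, 3) Å, fixed heavy-atom order
    energy: float  # kcal/mol docking score
    variant_label: str = "WT"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("pose coordinates must be finite")


@dataclass
class PoseCluster:
    representative: int  # pose_id of lowest-energy member
    members: list[int]
    representative_energy: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SelectionThreshold:
    mean: float
    sd: float
    n: int

    @property
    def cutoff(self) -> float:
        return self.mean - self.sd


@dataclass
class ScreenRecord:
    """Per-variant screening outcome (ΔG/ΔΔG in kcal/mol)."""

    variant_label: str
    delta_g: float | None = None
    delta_delta_g: float | None = None
    accepted_pose: int | None = None
    n_poses: int = 0
    n_accepted_clusters: int = 0
    reject_reasons: list[str] = field(default_factory=list)


def pose_rmsd(a: Pose, b: Pose) -> float:
    """RMSD between two poses without superposition (shared receptor frame)."""
    if a.coords.shape != b.coords.shape:
        raise ValueError(
            f"atom count mismatch: {a.coords.shape[0]} vs {b.coords.shape[0]}"
        )
    diff = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def cluster_poses(poses: Sequence[Pose], rmsd_tol: float = 2.0) -> list[PoseCluster]:
    """Leader clustering in ascending energy order.

    Poses are visited best-energy first (pose_id breaks ties); each joins
    the first existing cluster whose representative lies within
    ``rmsd_tol``, else opens a new cluster.  The result partitions the
    input; clusters come back ordered by representative energy.
    """
    by_id = {p.pose_id: p for p in poses}
    if len(by_id) != len(poses):
        raise ValueError("duplicate pose_ids")
    ordered = sorted(poses, key=lambda p: (p.energy, p.pose_id))
    clusters: list[PoseCluster] = []
    for pose in ordered:
        for cl in clusters:
            if pose_rmsd(pose, by_id[cl.representative]) <= rmsd_tol:
                cl.members.append(pose.pose_id)
                break
        else:
            clusters.append(
                PoseCluster(
                    representative=pose.pose_id,
                    members=[pose.pose_id],
                    representative_energy=pose.energy,
                )
            )
    return clusters


@dataclass
class FilterRules:
    """Geometric acceptance rules for a docked substrate pose.

    ``catalytic_resid``/``catalytic_atom`` locate the nucleophile probe
    (serine OG); a pose is accepted only if some ligand heavy atom lies
    strictly within ``catalytic_cutoff`` of it, and, for every entry of
    ``subsites`` (name -> residue numbers lining that part of the
    L-shaped cleft), some ligand atom lies within ``contact_cutoff`` of
    any atom of those residues.
    """

    catalytic_resid: int = 160
    catalytic_atom: str = "OG"
    catalytic_cutoff: float = 4.0
    subsites: Mapping[str, Sequence[int]] = field(default_factory=dict)
    contact_cutoff: float = 5.0


def _receptor_xyz(receptor: pd.DataFrame, mask) -> np.ndarray:
    return receptor.loc[mask, ["x", "y", "z"]].to_numpy(dtype=float)


def pose_filter(
    pose: Pose, receptor: pd.DataFrame, rules: FilterRules
) -> tuple[bool, list[str]]:
    """Apply the catalytic-distance and cleft-occupancy rules to one pose.

    ``receptor`` is an atom table with columns name/resid/x/y/z.  Returns
    ``(accepted, reasons)`` where reasons name each failed rule.
    """
    cat_mask = (receptor["resid"] == rules.catalytic_resid) & (
        receptor["name"] == rules.catalytic_atom
    )
    cat_xyz = _receptor_xyz(receptor, cat_mask)
    if len(cat_xyz) == 0:
        raise KeyError(
            f"catalytic atom {rules.catalytic_atom} of residue "
            f"{rules.catalytic_resid} not found in receptor"
        )
    reasons: list[str] = []
    d_cat = np.linalg.norm(pose.coords - cat_xyz[0], axis=1).min()
    if not d_cat < rules.catalytic_cutoff:
        reasons.append("catalytic_distance")
    for name, resids in rules.subsites.items():
        sub_xyz = _receptor_xyz(receptor, receptor["resid"].isin(list(resids)))
        if len(sub_xyz) == 0:
            raise KeyError(f"subsite {name!r} selects no receptor atoms")
        dmin = np.min(
            np.linalg.norm(
                pose.coords[:, None, :] - sub_xyz[None, :, :], axis=2
            )
        )
        if not dmin <= rules.contact_cutoff:
            reasons.append(f"subsite_{name}")
    return (not reasons), reasons


def select_delta_g(
    poses: Sequence[Pose],
    receptor: pd.DataFrame | None = None,
    rules: FilterRules | None = None,
    rmsd_tol: float = 2.0,
) -> ScreenRecord:
    """Cluster one variant's poses, filter representatives, take the best ΔG.

    With no receptor/rules every cluster is accepted.  If no cluster
    passes, ``delta_g`` is None and the record carries the failure
    reasons of the best-energy representative.
    """
    if not poses:
        raise ValueError("no poses supplied")
    labels = {p.variant_label for p in poses}
    if len(labels) > 1:
        raise ValueError(f"poses from multiple variants: {sorted(labels)}")
    by_id = {p.pose_id: p for p in poses}
    clusters = cluster_poses(poses, rmsd_tol=rmsd_tol)
    accepted: list[PoseCluster] = []
    first_reasons: list[str] = []
    for cl in clusters:
        if receptor is None or rules is None:
            ok, reasons = True, []
        else:
            ok, reasons = pose_filter(by_id[cl.representative], receptor, rules)
        if ok:
            accepted.append(cl)
        elif not first_reasons:
            first_reasons = reasons
    record = ScreenRecord(
        variant_label=labels.pop(),
        n_poses=len(poses),
        n_accepted_clusters=len(accepted),
    )
    if accepted:
        best = min(accepted, key=lambda c: (c.representative_energy, c.representative))
        record.delta_g = best.representative_energy
        record.accepted_pose = best.representative
    else:
        record.reject_reasons = first_reasons or ["no_accepted_cluster"]
    return record


def delta_delta_g(dg_variant: float | None, dg_wt: float | None) -> float | None:
    """ΔΔG = ΔG(variant) − ΔG(WT); None propagates."""
    if dg_variant is None or dg_wt is None:
        return None
    return dg_variant - dg_wt


def selection_threshold(values: Iterable[float]) -> SelectionThreshold:
    """Mean and sample SD (n−1) of the ΔΔG values; cutoff = mean − SD."""
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size < 2:
        raise ValueError("selection threshold needs at least 2 values")
    return SelectionThreshold(
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size)
    )


def nominate_candidates(
    records: Sequence[ScreenRecord], threshold: SelectionThreshold
) -> list[ScreenRecord]:
    """Records with ΔΔG strictly below the cutoff, sorted ascending."""
    hits = [
        r
        for r in records
        if r.delta_delta_g is not None and r.delta_delta_g < threshold.cutoff
    ]
    return sorted(hits, key=lambda r: (r.delta_delta_g, r.variant_label))


def records_to_frame(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    from .variants import Variant

    rows = []
    for r in records:
        rows.append(
            {
                "label": r.variant_label,
                "r": Variant.from_label(r.variant_label).n_sites,
                "delta_g": r.delta_g,
                "delta_delta_g": r.delta_delta_g,
                "accepted_pose": r.accepted_pose,
                "n_poses": r.n_poses,
                "n_accepted_clusters": r.n_accepted_clusters,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pose IO.  TSV (long form) is the primary exchange format; multi-model PDB
# with a per-MODEL energy REMARK (docking-engine convention) is also offered.
# ---------------------------------------------------------------------------

def poses_to_tsv(poses: Sequence[Pose], path) -> None:
    rows = []
    for p in poses:
        for i, (x, y, z) in enumerate(p.coords):
            rows.append(
                {
                    "pose_id": p.pose_id,
                    "variant_label": p.variant_label,
                    "energy": p.energy,
                    "atom_index": i,
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def poses_from_tsv(path) -> list[Pose]:
    df = pd.read_csv(path, sep="\t")
    poses = []
    for (pid, label, energy), grp in df.groupby(
        ["pose_id", "variant_label", "energy"], sort=False
    ):
        grp = grp.sort_values("atom_index")
        poses.append(
            Pose(
                pose_id=int(pid),
                coords=grp[["x", "y", "z"]].to_numpy(dtype=float),
                energy=float(energy),
                variant_label=str(label),
            )
        )
    return poses


def poses_to_pdb(poses: Sequence[Pose], path, resname: str = "PET") -> None:
    """Write poses as a multi-model PDB, one MODEL per pose.

    Each MODEL is preceded by ``REMARK 200 ENERGY`` and
    ``REMARK 200 VARIANT`` lines; atoms are generic carbons C1..CN.
    """
    with open(path, "w") as fh:
        for p in poses:
            fh.write(f"MODEL     {p.pose_id:>4d}\n")
            fh.write(f"REMARK 200 ENERGY {p.energy:.4f}\n")
            fh.write(f"REMARK 200 VARIANT {p.variant_label}\n")
            for i, (x, y, z) in enumerate(p.coords, start=1):
                fh.write(
                    f"ATOM  {i:>5d} {('C%d' % i):<4s}{resname:>4s} L   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def poses_from_pdb(path) -> list[Pose]:
    poses: list[Pose] = []
    pose_id, energy, label, coords = None, None, "WT", []
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                pose_id, energy, label, coords = int(line[6:].strip()), None, "WT", []
            elif rec == "REMARK" and "ENERGY" in line:
                energy = float(line.split()[-1])
            elif rec == "REMARK" and "VARIANT" in line:
                label = line.split()[-1]
            elif rec in ("ATOM", "HETATM"):
                coords.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
            elif rec == "ENDMDL":
                if energy is None:
                    raise ValueError(f"pose {pose_id} has no ENERGY remark")
                poses.append(
                    Pose(
                        pose_id=pose_id,
                        coords=np.array(coords),
                        energy=energy,
                        variant_label=label,
                    )
                )
    return poses


def read_receptor_pdb(path) -> pd.DataFrame:
    """Read a receptor PDB into an atom table (biotite-backed)."""
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    return pd.DataFrame(
        {
            "name": arr.atom_name,
            "resname": arr.res_name,
            "chain": arr.chain_id,
            "resid": arr.res_id,
            "element": arr.element,
            "x": arr.coord[:, 0],
            "y": arr.coord[:, 1],
            "z": arr.coord[:, 2],
        }
    )
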