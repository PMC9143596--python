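"""End-to-end reverse screen orchestration.

The screen runs: candidate-site nomination -> single-site alanine scan ->
selection threshold (mean − SD of ΔΔG) -> combinatorial alanine scan over
the nominated sites -> sequence-space maps -> single/double
site-saturation -> final candidate report.  Docking energies come either
from a (synthetic or engine-exported) variant -> ΔG table or from raw
pose sets put through clustering and geometric filtering.

Every stage is a pure function of its declared inputs; reports embed a
hash of the resolved configuration so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import docking, mmpbsa, msa, seqspace, synthetic, variants
from .docking import ScreenRecord, records_to_frame
from .variants import Variant

log = logging.getLogger("petscreen")

#: Docking-engine settings recorded as provenance only (never executed):
#: grid box and genetic-algorithm parameters of the original screen.
ENGINE_PROVENANCE = {
    "engine": "AutoDock4.2 (external)",
    "grid_box_A3": [120, 90, 120],
    "grid_center": [-2.403, 30.711, -18.311],
    "grid_spacing_A": 0.375,
    "lga_population": 200,
    "lga_generations": 27000,
    "lga_energy_evaluations": 2500000,
    "docking_runs": 500,
}


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    rmsd_tol: float = 2.0  # Å, pose leader clustering
    catalytic_cutoff: float = 4.0  # Å, ligand to serine-OG acceptance
    contact_cutoff: float = 5.0  # Å, cleft subsite occupancy
    score_cutoff: int = 6  # conservation score gate (strict <)
    n_snapshots: int = 500  # MM/PBSA snapshot count
    max_selected_sites: int = 8
    double_ssm_sites: tuple[int, int] = synthetic.DOUBLE_SSM_SITES
    noise_sd: float = 0.2  # kcal/mol, synthetic landscape noise
    seed: int = 0
    provenance: dict = field(default_factory=lambda: dict(ENGINE_PROVENANCE))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def screen_with_landscape(
    library: variants.Library, landscape: synthetic.Landscape
) -> list[ScreenRecord]:
    """Score every library variant on a landscape; ΔΔG is taken vs the WT."""
    dg_wt = landscape.delta_g(Variant())
    records = []
    for v in library:
        dg = landscape.delta_g(v)
        records.append(
            ScreenRecord(
                variant_label=v.label,
                delta_g=dg,
                delta_delta_g=docking.delta_delta_g(dg, dg_wt),
            )
        )
    return records


def screen_from_poses(
    pose_sets: Mapping[str, Sequence[docking.Pose]],
    receptor: pd.DataFrame | None = None,
    rules: docking.FilterRules | None = None,
    rmsd_tol: float = 2.0,
    wt_label: str = "WT",
) -> list[ScreenRecord]:
    """Reduce per-variant pose sets to ScreenRecords (cluster, filter, ΔΔG)."""
    if wt_label not in pose_sets:
        raise KeyError(f"pose sets lack the WT entry {wt_label!r}")
    records = {
        label: docking.select_delta_g(
            poses, receptor=receptor, rules=rules, rmsd_tol=rmsd_tol
        )
        for label, poses in pose_sets.items()
    }
    dg_wt = records[wt_label].delta_g
    for rec in records.values():
        rec.delta_delta_g = docking.delta_delta_g(rec.delta_g, dg_wt)
    return list(records.values())


def run_reverse_screen(
    landscape: synthetic.Landscape,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Full synthetic reverse screen; returns (and optionally writes) the report.

    Stages: single-site alanine scan over every candidate site ->
    mean − SD threshold -> nominated sites -> combinatorial alanine scan
    -> mutation-count / fixed-site maps -> single SSM per nominated site
    -> double SSM on the configured site pair -> class map -> report
    naming the best single and double variants.
    """
    cfg = config or RunConfig()
    wt = landscape.wt_residues
    scannable = [s for s in landscape.sites if wt[s] != "A"]

    # Stage 1: single-site alanine scan.
    asm_single = variants.alanine_combinatorial(
        scannable, wt, r_min=1, r_max=1, catalytic=synthetic.CATALYTIC_TRIAD
    )
    asm_records = screen_with_landscape(asm_single, landscape)
    threshold = docking.selection_threshold(
        [r.delta_delta_g for r in asm_records]
    )
    nominated = docking.nominate_candidates(asm_records, threshold)
    n_negative = sum(1 for r in asm_records if r.delta_delta_g < 0)
    selected_sites = sorted(
        Variant.from_label(r.variant_label).positions[0]
        for r in nominated[: cfg.max_selected_sites]
    )
    log.info(
        "alanine scan: %d variants, %d negative ΔΔG, threshold %.3f, "
        "%d sites nominated",
        len(asm_records), n_negative, threshold.cutoff, len(selected_sites),
    )

    # Stage 2: combinatorial alanine scan over the nominated sites.
    asm_comb = variants.alanine_combinatorial(
        selected_sites, wt, catalytic=synthetic.CATALYTIC_TRIAD
    )
    comb_records = screen_with_landscape(asm_comb, landscape)
    comb_frame = records_to_frame(comb_records)
    count_map = seqspace.map_by_mutation_count(comb_frame)
    site_map = seqspace.fixed_site_map(comb_frame, selected_sites)
    best_r = int(
        count_map.table.loc[count_map.table["min"].idxmin(), "r"]
    )

    # Stage 3: single-site saturation at each nominated site.
    ssm_records: list[ScreenRecord] = []
    for site in selected_sites:
        lib = variants.ssm_single(
            site, wt[site], include_wt=False,
            catalytic=synthetic.CATALYTIC_TRIAD,
        )
        ssm_records.extend(screen_with_landscape(lib, landscape))
    best_single = min(ssm_records, key=lambda r: (r.delta_delta_g, r.variant_label))

    # Stage 4: double saturation on the configured pair.
    site_a, site_b = cfg.double_ssm_sites
    ssm2 = variants.ssm_double(
        site_a, site_b, wt[site_a], wt[site_b],
        catalytic=synthetic.CATALYTIC_TRIAD,
    )
    ssm2_records = screen_with_landscape(ssm2, landscape)
    cmap = seqspace.class_map(
        records_to_frame(ssm2_records), [site_a, site_b], wt
    )
    doubles = [r for r in ssm2_records if "/" in r.variant_label]
    best_double = min(doubles, key=lambda r: (r.delta_delta_g, r.variant_label))

    report = {
        "config_hash": cfg.config_hash(),
        "n_candidate_sites": len(scannable),
        "asm_single_variants": len(asm_single),
        "n_negative_ddg": n_negative,
        "threshold_mean": threshold.mean,
        "threshold_sd": threshold.sd,
        "threshold_cutoff": threshold.cutoff,
        "selected_sites": selected_sites,
        "asm_combinatorial_variants": len(asm_comb),
        "asm_size_by_r": asm_comb.size_by_r(),
        "best_mutation_count": best_r,
        "ssm_single_variants": len(ssm_records),
        "best_single": best_single.variant_label,
        "best_single_ddg": best_single.delta_delta_g,
        "ssm_double_variants": len(ssm2_records),
        "best_double": best_double.variant_label,
        "best_double_ddg": best_double.delta_delta_g,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_to_frame(asm_records).to_csv(
            out / "asm_single.tsv", sep="\t", index=False
        )
        comb_frame.to_csv(out / "asm_combinatorial.tsv", sep="\t", index=False)
        records_to_frame(ssm_records).to_csv(
            out / "ssm_single.tsv", sep="\t", index=False
        )
        records_to_frame(ssm2_records).to_csv(
            out / "ssm_double.tsv", sep="\t", index=False
        )
        count_map.to_tsv(out / "map_by_mutation_count.tsv")
        site_map.to_tsv(out / "map_fixed_site.tsv")
        cmap.to_tsv(out / "map_class_double.tsv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# Named stages (CLI surface)
# ---------------------------------------------------------------------------

def run_stage(name: str, config: Mapping, out_dir: str | Path) -> dict:
    """Run one named stage from a plain configuration mapping.

    Stages: ``simulate`` (emit synthetic inputs), ``sites`` (conservation
    + nomination), ``asm`` / ``asm-iter`` / ``ssm`` (library
    enumeration), ``screen`` (ΔG table or poses -> records + threshold),
    ``space`` (maps from a records TSV), ``md`` (trajectory ->
    RMSD/RMSF/distance tables), ``mmpbsa`` (component tables -> binding
    summary), ``run-all`` (synthetic end-to-end).  Each returns
    a small report dict and writes TSV/JSON outputs under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(
        seed=int(config.get("seed", 0)),
        noise_sd=float(config.get("noise_sd", 0.2)),
    )
    handlers = {
        "simulate": _stage_simulate,
        "sites": _stage_sites,
        "asm": _stage_asm,
        "asm-iter": _stage_asm_iter,
        "ssm": _stage_ssm,
        "screen": _stage_screen,
        "space": _stage_space,
        "md": _stage_md,
        "mmpbsa": _stage_mmpbsa,
        "run-all": _stage_run_all,
    }
    if name not in handlers:
        raise ValueError(f"unknown stage {name!r}; choose from {sorted(handlers)}")
    report = handlers[name](dict(config), cfg, out)
    report["stage"] = name
    report["config_hash"] = cfg.config_hash()
    with open(out / f"{name.replace('-', '_')}_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report


def _require(config: Mapping, key: str, stage: str, hint: str) -> str:
    if key not in config:
        raise ValueError(
            f"stage {stage!r} needs config key {key!r} ({hint})"
        )
    return config[key]


def _stage_simulate(config, cfg, out) -> dict:
    seed = cfg.seed
    aln = synthetic.gen_alignment(seed=seed)
    msa.write_alignment(aln, out / "alignment.fasta")
    poses, labels, _ = synthetic.gen_pose_set(
        k_clusters=3, spread=0.5, n_poses=30, seed=seed
    )
    docking.poses_to_tsv(poses, out / "poses.tsv")
    traj, sigma = synthetic.gen_trajectory(
        synthetic.TrajectoryConfig(n_residues=30, n_frames=100, seed=seed)
    )
    traj.to_pdb(out / "trajectory.pdb")
    frames = synthetic.gen_energy_frames(
        delta_means={"vdw": -160.0, "electrostatic": -32.0, "polar": 94.0,
                     "apolar": -20.0},
        delta_sds={"vdw": 18.0, "electrostatic": 19.0, "polar": 38.0,
                   "apolar": 2.0},
        n=100, seed=seed,
    )
    mmpbsa.frames_to_tsv(frames, out / "energy_frames.tsv")
    return {
        "alignment": "alignment.fasta", "poses": "poses.tsv",
        "trajectory": "trajectory.pdb", "energy_frames": "energy_frames.tsv",
        "seed": seed,
    }


def _stage_sites(config, cfg, out) -> dict:
    aln = msa.read_alignment(
        _require(config, "alignment", "sites", "aligned FASTA path"),
        ref_id=config.get("ref_id"),
    )
    site_config = config.get("site_config")
    if site_config:
        with open(site_config) as fh:
            import yaml

            entries = yaml.safe_load(fh)
        annotations = msa.annotations_from_config(entries, aln)
        annotations = msa.nominate_sites(
            annotations,
            score_cutoff=int(config.get("score_cutoff", cfg.score_cutoff)),
            overrides=config.get("overrides", ()),
        )
        msa.annotations_to_frame(annotations).to_csv(
            out / "site_annotations.tsv", sep="\t", index=False
        )
        nominated = [a.residue_number for a in annotations if a.nominated]
    else:
        nominated = []
    scores, flags = msa.column_conservation(aln)
    pd.DataFrame(
        {"column": range(1, len(scores) + 1), "conservation": scores,
         "low_confidence": flags}
    ).to_csv(out / "conservation.tsv", sep="\t", index=False)
    return {"n_columns": len(scores), "nominated_sites": nominated}


def _stage_asm(config, cfg, out) -> dict:
    sites, wt = _sites_and_wt(config)
    lib = variants.alanine_combinatorial(
        sites, wt, r_min=1, r_max=1, catalytic=synthetic.CATALYTIC_TRIAD
    )
    lib.to_tsv(out / "asm_single_library.tsv")
    return {"n_variants": len(lib)}


def _stage_asm_iter(config, cfg, out) -> dict:
    sites, wt = _sites_and_wt(config)
    lib = variants.alanine_combinatorial(
        sites, wt, catalytic=synthetic.CATALYTIC_TRIAD
    )
    lib.to_tsv(out / "asm_combinatorial_library.tsv")
    return {"n_variants": len(lib), "size_by_r": lib.size_by_r()}


def _stage_ssm(config, cfg, out) -> dict:
    sites, wt = _sites_and_wt(config)
    report: dict = {}
    singles = []
    for site in sites:
        lib = variants.ssm_single(
            site, wt[site], catalytic=synthetic.CATALYTIC_TRIAD
        )
        singles.append(lib)
    if singles:
        pd.concat([lib.to_frame() for lib in singles]).drop_duplicates(
            "label"
        ).to_csv(out / "ssm_single_library.tsv", sep="\t", index=False)
        report["ssm_single_per_site"] = {
            str(lib.sites[0]): len(lib) for lib in singles
        }
    pair = config.get("double_sites")
    if pair:
        a, b = int(pair[0]), int(pair[1])
        lib2 = variants.ssm_double(
            a, b, wt[a], wt[b], catalytic=synthetic.CATALYTIC_TRIAD
        )
        lib2.to_tsv(out / "ssm_double_library.tsv")
        report["ssm_double_variants"] = len(lib2)
    return report


def _stage_screen(config, cfg, out) -> dict:
    if "delta_g_table" in config:
        df = pd.read_csv(config["delta_g_table"], sep="\t")
        wt_rows = df[df["label"] == "WT"]
        if wt_rows.empty:
            raise ValueError("ΔG table has no WT row")
        dg_wt = float(wt_rows["delta_g"].iloc[0])
        records = [
            ScreenRecord(
                variant_label=str(row["label"]),
                delta_g=float(row["delta_g"]),
                delta_delta_g=float(row["delta_g"]) - dg_wt,
            )
            for _, row in df.iterrows()
        ]
    else:
        pose_path = _require(
            config, "poses", "screen", "pose TSV (or give delta_g_table)"
        )
        poses = docking.poses_from_tsv(pose_path)
        sets: dict[str, list[docking.Pose]] = {}
        for p in poses:
            sets.setdefault(p.variant_label, []).append(p)
        receptor = rules = None
        if "receptor" in config:
            receptor = docking.read_receptor_pdb(config["receptor"])
            rules = docking.FilterRules(
                catalytic_cutoff=float(
                    config.get("catalytic_cutoff", cfg.catalytic_cutoff)
                ),
                contact_cutoff=float(
                    config.get("contact_cutoff", cfg.contact_cutoff)
                ),
                subsites=config.get("subsites", {}),
            )
        records = screen_from_poses(
            sets, receptor=receptor, rules=rules,
            rmsd_tol=float(config.get("rmsd_tol", cfg.rmsd_tol)),
        )
    non_wt = [r for r in records if r.variant_label != "WT"]
    threshold = docking.selection_threshold(
        [r.delta_delta_g for r in non_wt if r.delta_delta_g is not None]
    )
    nominated = docking.nominate_candidates(non_wt, threshold)
    records_to_frame(records).to_csv(
        out / "screen_records.tsv", sep="\t", index=False
    )
    return {
        "n_variants": len(records),
        "threshold_mean": threshold.mean,
        "threshold_sd": threshold.sd,
        "threshold_cutoff": threshold.cutoff,
        "nominated": [r.variant_label for r in nominated],
    }


def _stage_space(config, cfg, out) -> dict:
    df = pd.read_csv(
        _require(config, "records", "space", "screen records TSV"), sep="\t"
    )
    count_map = seqspace.map_by_mutation_count(df)
    count_map.to_tsv(out / "map_by_mutation_count.tsv")
    report = {"n_records": len(df)}
    if "sites" in config:
        sites = [int(s) for s in config["sites"]]
        site_map = seqspace.fixed_site_map(df, sites)
        site_map.to_tsv(out / "map_fixed_site.tsv")
        report["fixed_site_cells"] = len(site_map.table)
    return report


def _stage_md(config, cfg, out) -> dict:
    from .md import Trajectory, distance_series, rmsd_series, rmsf_per_residue

    traj = Trajectory.from_pdb(
        _require(config, "trajectory", "md", "multi-model PDB path"),
        dt=float(config.get("dt", 10.0)),
    )
    series = rmsd_series(traj, stride=int(config.get("stride", 1)))
    series.to_csv(out / "rmsd_series.tsv", sep="\t", index=False)
    rmsf = rmsf_per_residue(traj, window=config.get("window", "last_half"))
    rmsf.rename_axis("resid").reset_index().to_csv(
        out / "rmsf_per_residue.tsv", sep="\t", index=False
    )
    report = {
        "n_frames": traj.n_frames,
        "n_atoms": traj.n_atoms,
        "rmsd_final": float(series["rmsd"].iloc[-1]),
        "rmsf_max_resid": int(rmsf.idxmax()),
    }
    if "distance_probe" in config:
        d = distance_series(
            traj, config["distance_probe"], config["distance_targets"]
        )
        d.to_csv(out / "distance_series.tsv", sep="\t", index=False)
        report["closest_atom_final"] = str(d["closest"].iloc[-1])
    return report


def _stage_mmpbsa(config, cfg, out) -> dict:
    frames = mmpbsa.frames_from_tsv(
        _require(config, "energy_frames", "mmpbsa", "component TSV"),
        residue_path=config.get("residue_frames"),
    )
    summary = mmpbsa.summarize(frames)
    summary.to_frame().to_csv(out / "binding_summary.tsv", sep="\t", index=False)
    return {
        "n_snapshots": summary.n_snapshots,
        "total_mean": summary.total_mean,
        "total_sd": summary.total_sd,
    }


def _stage_run_all(config, cfg, out) -> dict:
    landscape = synthetic.default_landscape(
        seed=cfg.seed, noise_sd=cfg.noise_sd
    )
    return run_reverse_screen(landscape, cfg, out_dir=out)


def _sites_and_wt(config) -> tuple[list[int], dict[int, str]]:
    entries = config.get("sites")
    if not entries:
        raise ValueError(
            "config needs 'sites': list of {residue_number, wt} entries"
        )
    sites, wt = [], {}
    for e in entries:
        res = int(e["residue_number"])
        sites.append(res)
        wt[res] = str(e["wt"])
    return sites, wt
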