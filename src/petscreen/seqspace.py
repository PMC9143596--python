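"""Sequence-space summaries of screening results.

Aggregates per-variant ΔΔG into the maps used to read the screen:
distribution by mutation count, fixed-site maps over the combinatorial
alanine scan ("does any variant containing this site improve?"), and
physicochemical-class maps for single/double site-saturation grids.

Residue classes P1–P6 partition the 20 standard amino acids (default:
P1 small aliphatic, P2 aromatic, P3 polar uncharged, P4 positive,
P5 negative, P6 special/empty).  The table is editable data and every
map records the table it was built with.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .variants import STANDARD_AA, Variant

_AGGREGATORS = {"min": np.min, "mean": np.mean, "median": np.median}


def load_residue_classes(path=None) -> dict[str, frozenset[str]]:
    """Load the class table (class id -> residue set) and check it partitions."""
    src = (
        path
        if path is not None
        else importlib.resources.files("petscreen.data").joinpath(
            "residue_classes.yaml"
        )
    )
    with open(src) as fh:
        raw = yaml.safe_load(fh)
    table = {cid: frozenset(entry["members"]) for cid, entry in raw.items()}
    validate_class_partition(table)
    return table


def validate_class_partition(table: Mapping[str, frozenset[str]]) -> None:
    seen: dict[str, str] = {}
    for cid, members in table.items():
        for aa in members:
            if aa in seen:
                raise ValueError(f"{aa} in both {seen[aa]} and {cid}")
            seen[aa] = cid
    missing = set(STANDARD_AA) - set(seen)
    if missing:
        raise ValueError(f"residues not classified: {sorted(missing)}")


def classify_residue(aa: str, table: Mapping[str, frozenset[str]] | None = None) -> str:
    """Class id (P1..P6) of a standard amino acid."""
    if aa not in STANDARD_AA:
        raise ValueError(f"non-standard amino acid {aa!r}")
    if table is None:
        table = load_residue_classes()
    for cid, members in table.items():
        if aa in members:
            return cid
    raise ValueError(f"{aa!r} not covered by the class table")


@dataclass
class SpaceMap:
    """A long-form aggregated map: axis columns + aggregate + n per cell."""

    kind: str
    axes: list[str]
    table: pd.DataFrame
    aggregator: str
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "kind": self.kind,
            "axes": self.axes,
            "aggregator": self.aggregator,
            "n_excluded": self.n_excluded,
            "meta": self.meta,
            "cells": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _records_frame(records) -> pd.DataFrame:
    """Normalise input (DataFrame or ScreenRecord list) to label/r/ddg rows."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        from .docking import records_to_frame

        df = records_to_frame(records)
    if "r" not in df.columns:
        df["r"] = [Variant.from_label(l).n_sites for l in df["label"]]
    return df


def map_by_mutation_count(records) -> SpaceMap:
    """ΔΔG distribution summary per mutation count r (n, min, quartiles, mean)."""
    df = _records_frame(records)
    defined = df[df["delta_delta_g"].notna()]
    n_excluded = len(df) - len(defined)
    rows = []
    for r in sorted(df["r"].unique()):
        vals = defined.loc[defined["r"] == r, "delta_delta_g"].to_numpy(dtype=float)
        if vals.size:
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            rows.append(
                dict(r=int(r), n=int(vals.size), min=vals.min(), q25=q25,
                     median=q50, q75=q75, mean=vals.mean(), max=vals.max())
            )
        else:
            rows.append(dict(r=int(r), n=0, min=np.nan, q25=np.nan,
                             median=np.nan, q75=np.nan, mean=np.nan, max=np.nan))
    return SpaceMap(
        kind="by_mutation_count",
        axes=["r"],
        table=pd.DataFrame(rows),
        aggregator="summary",
        n_excluded=n_excluded,
    )


def fixed_site_map(records, sites: Sequence[int], aggregator: str = "min") -> SpaceMap:
    """Matrix (r, site): aggregate ΔΔG over size-r variants containing the site.

    Each size-r variant contributes to exactly r cells of row r.  Sites
    present in no record yield empty (NaN, n=0) cells, flagged in meta.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    agg = _AGGREGATORS[aggregator]
    df = _records_frame(records)
    defined = df[df["delta_delta_g"].notna()]
    n_excluded = len(df) - len(defined)
    positions = [Variant.from_label(l).positions for l in defined["label"]]
    rows = []
    seen_sites = set()
    for r in sorted(defined["r"].unique()):
        if r == 0:
            continue
        mask = (defined["r"] == r).to_numpy()
        vals_r = defined["delta_delta_g"].to_numpy(dtype=float)[mask]
        pos_r = [p for p, m in zip(positions, mask) if m]
        for site in sites:
            cell = np.array(
                [v for v, p in zip(vals_r, pos_r) if site in p], dtype=float
            )
            if cell.size:
                seen_sites.add(site)
            rows.append(
                dict(
                    r=int(r),
                    site=int(site),
                    aggregate=float(agg(cell)) if cell.size else np.nan,
                    n=int(cell.size),
                )
            )
    empty = sorted(set(sites) - seen_sites)
    return SpaceMap(
        kind="fixed_site",
        axes=["r", "site"],
        table=pd.DataFrame(rows),
        aggregator=aggregator,
        n_excluded=n_excluded,
        meta={"empty_sites": empty},
    )


def class_map(
    records,
    site_axes: Sequence[int],
    wt_residues: Mapping[int, str],
    aggregator: str = "mean",
    class_table: Mapping[str, frozenset[str]] | None = None,
) -> SpaceMap:
    """Physicochemical-class map for single or double SSM records.

    One site axis: cells are (site residue class) x site.  Two site
    axes: a 6x6 class-aggregated matrix; the underlying 20x20 amino-acid
    matrix (ordered by class, then alphabetically) is attached in
    ``meta["aa_matrix"]``.  WT rows contribute at their WT identities.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    agg = _AGGREGATORS[aggregator]
    if class_table is None:
        class_table = load_residue_classes()
    else:
        validate_class_partition(class_table)
    class_of = {aa: classify_residue(aa, class_table) for aa in STANDARD_AA}
    class_ids = list(class_table.keys())

    df = _records_frame(records)
    defined = df[df["delta_delta_g"].notna()].copy()
    n_excluded = len(df) - len(defined)
    for site in site_axes:
        defined[f"aa_{site}"] = [
            Variant.from_label(l).aa_at(site, wt_residues) for l in defined["label"]
        ]
        defined[f"class_{site}"] = defined[f"aa_{site}"].map(class_of)

    cls_cols = [f"class_{s}" for s in site_axes]
    rows = []
    if len(site_axes) == 1:
        for cid in class_ids:
            vals = defined.loc[
                defined[cls_cols[0]] == cid, "delta_delta_g"
            ].to_numpy(dtype=float)
            rows.append(
                dict(
                    **{cls_cols[0]: cid},
                    aggregate=float(agg(vals)) if vals.size else np.nan,
                    n=int(vals.size),
                )
            )
    elif len(site_axes) == 2:
        for cid_a in class_ids:
            for cid_b in class_ids:
                vals = defined.loc[
                    (defined[cls_cols[0]] == cid_a)
                    & (defined[cls_cols[1]] == cid_b),
                    "delta_delta_g",
                ].to_numpy(dtype=float)
                rows.append(
                    dict(
                        **{cls_cols[0]: cid_a, cls_cols[1]: cid_b},
                        aggregate=float(agg(vals)) if vals.size else np.nan,
                        n=int(vals.size),
                    )
                )
    else:
        raise ValueError("class_map supports one or two site axes")

    meta: dict = {
        "class_table": {cid: sorted(m) for cid, m in class_table.items()},
        "sites": list(site_axes),
    }
    if len(site_axes) == 2:
        order = sorted(STANDARD_AA, key=lambda aa: (class_of[aa], aa))
        aa_matrix = pd.DataFrame(np.nan, index=order, columns=order)
        for _, row in defined.iterrows():
            aa_matrix.loc[row[f"aa_{site_axes[0]}"], row[f"aa_{site_axes[1]}"]] = row[
                "delta_delta_g"
            ]
        meta["aa_matrix"] = aa_matrix
    return SpaceMap(
        kind=f"class_map_{len(site_axes)}site",
        axes=cls_cols,
        table=pd.DataFrame(rows),
        aggregator=aggregator,
        n_excluded=n_excluded,
        meta=meta,
    )
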