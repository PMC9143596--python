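"""Variant library enumeration for alanine-scanning and site-saturation mutagenesis.

A :class:`Variant` is a sparse set of substitutions on a reference enzyme
(empty set = wild type).  Libraries are built three ways:

* combinatorial alanine scanning — every subset of the candidate sites,
  each chosen site replaced by Ala (``C(n, r)`` variants per subset size);
* single-site saturation — one site replaced by each of the 19 non-WT
  standard amino acids (20 rows when the WT record is included);
* double-site saturation — the full 20 x 20 grid over two sites, which
  contains one WT row, 38 single-substitution rows and 361 doubles.

Catalytic-triad residues are never mutated; validation enforces this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The 20 standard amino acids, one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def count_combinations(n: int, r: int) -> int:
    """Exact binomial coefficient ``n! / ((n-r)! r!)``.

    Raises ``ValueError`` for negative arguments or ``r > n``.
    """
    if n < 0 or r < 0 or r > n:
        raise ValueError(f"require 0 <= r <= n, got n={n}, r={r}")
    return math.comb(n, r)


@dataclass(frozen=True)
class Variant:
    """A sparse substitution set: ``((position, wt_aa, new_aa), ...)`` sorted by position.

    The canonical label joins per-site substitutions with "/" in ascending
    position order, e.g. ``"D112M/S238F"``; the empty variant is ``"WT"``.
    """

    substitutions: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        subs = tuple(sorted(self.substitutions, key=lambda s: s[0]))
        positions = [s[0] for s in subs]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate positions in {subs}")
        for pos, wt, new in subs:
            if wt == new:
                raise ValueError(f"self-substitution {wt}{pos}{new}")
            for aa in (wt, new):
                if aa not in STANDARD_AA:
                    raise ValueError(f"non-standard amino acid {aa!r} at {pos}")
        object.__setattr__(self, "substitutions", subs)

    @property
    def label(self) -> str:
        if not self.substitutions:
            return "WT"
        return "/".join(f"{wt}{pos}{new}" for pos, wt, new in self.substitutions)

    @property
    def n_sites(self) -> int:
        return len(self.substitutions)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s[0] for s in self.substitutions)

    def aa_at(self, position: int, wt_residues: Mapping[int, str] | None = None) -> str:
        """Amino acid at ``position`` (falls back to WT identity if known)."""
        for pos, _wt, new in self.substitutions:
            if pos == position:
                return new
        if wt_residues is not None and position in wt_residues:
            return wt_residues[position]
        raise KeyError(f"position {position} not substituted and WT identity unknown")

    @classmethod
    def from_label(cls, label: str) -> "Variant":
        """Parse a canonical label such as ``"D112M/S238F"`` (or ``"WT"``)."""
        label = label.strip()
        if label in ("", "WT"):
            return cls()
        subs = []
        for token in label.split("/"):
            wt, pos, new = token[0], int(token[1:-1]), token[-1]
            subs.append((pos, wt, new))
        return cls(tuple(subs))


def _check_sites(
    sites: Sequence[int], catalytic: Iterable[int]
) -> None:
    if len(set(sites)) != len(sites):
        raise ValueError(f"duplicate sites in {list(sites)}")
    bad = sorted(set(sites) & set(catalytic))
    if bad:
        raise ValueError(f"catalytic residues may not be mutated: {bad}")


@dataclass
class Library:
    """An ordered, duplicate-free list of variants plus its construction metadata."""

    variants: list[Variant]
    scheme: str
    sites: list[int]
    includes_wt: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [v.label for v in self.variants]
        if len(set(labels)) != len(labels):
            seen, dups = set(), set()
            for lab in labels:
                (dups if lab in seen else seen).add(lab)
            raise ValueError(f"duplicate variant labels: {sorted(dups)}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def labels(self) -> list[str]:
        return [v.label for v in self.variants]

    def size_by_r(self) -> dict[int, int]:
        """Number of variants per substitution count r."""
        out: dict[int, int] = {}
        for v in self.variants:
            out[v.n_sites] = out.get(v.n_sites, 0) + 1
        return dict(sorted(out.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "r": [v.n_sites for v in self.variants]}
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "scheme", self.scheme)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Library":
        df = pd.read_csv(path, sep="\t")
        variants = [Variant.from_label(lab) for lab in df["label"]]
        scheme = str(df["scheme"].iloc[0]) if "scheme" in df and len(df) else "unknown"
        sites = sorted({p for v in variants for p in v.positions})
        return cls(
            variants=variants,
            scheme=scheme,
            sites=sites,
            includes_wt=any(v.n_sites == 0 for v in variants),
        )


def alanine_combinatorial(
    sites: Sequence[int],
    wt_residues: Mapping[int, str],
    r_min: int = 1,
    r_max: int | None = None,
    catalytic: Iterable[int] = (),
) -> Library:
    """Every subset of ``sites`` of size r in [r_min, r_max], all chosen sites -> Ala.

    With 8 sites and the full range this yields 8/28/56/70/56/28/8/1
    variants for r = 1..8, i.e. 255 in total (2^8 - 1).  Sites whose WT
    residue is already alanine are rejected at input.
    """
    _check_sites(sites, catalytic)
    for s in sites:
        if s not in wt_residues:
            raise ValueError(f"no WT residue given for site {s}")
        if wt_residues[s] == "A":
            raise ValueError(f"site {s} is already alanine in the WT")
    if r_max is None:
        r_max = len(sites)
    if not (1 <= r_min <= r_max <= len(sites)):
        raise ValueError(f"require 1 <= r_min <= r_max <= {len(sites)}")
    ordered = sorted(sites)
    variants: list[Variant] = []
    for r in range(r_min, r_max + 1):
        batch = [
            Variant(tuple((s, wt_residues[s], "A") for s in combo))
            for combo in combinations(ordered, r)
        ]
        batch.sort(key=lambda v: v.label)
        variants.extend(batch)
    return Library(
        variants=variants,
        scheme="asm_combinatorial",
        sites=list(ordered),
        includes_wt=False,
        meta={"r_min": r_min, "r_max": r_max},
    )


def ssm_single(
    site: int,
    wt_residue: str,
    include_wt: bool = True,
    catalytic: Iterable[int] = (),
) -> Library:
    """Site-saturation at one position: 19 substitution variants (+ WT row if asked)."""
    _check_sites([site], catalytic)
    if wt_residue not in STANDARD_AA:
        raise ValueError(f"non-standard WT residue {wt_residue!r}")
    variants: list[Variant] = [Variant()] if include_wt else []
    variants += [
        Variant(((site, wt_residue, aa),)) for aa in STANDARD_AA if aa != wt_residue
    ]
    return Library(
        variants=variants,
        scheme="ssm_single",
        sites=[site],
        includes_wt=include_wt,
    )


def ssm_double(
    site_a: int,
    site_b: int,
    wt_a: str,
    wt_b: str,
    catalytic: Iterable[int] = (),
) -> Library:
    """Full 20 x 20 saturation grid over two positions (400 rows incl. one WT).

    The grid partitions into 1 WT + 2*19 single-substitution + 19^2
    double-substitution records.
    """
    if site_a == site_b:
        raise ValueError("site_a and site_b must differ")
    _check_sites([site_a, site_b], catalytic)
    for wt in (wt_a, wt_b):
        if wt not in STANDARD_AA:
            raise ValueError(f"non-standard WT residue {wt!r}")
    variants = []
    for aa_a in STANDARD_AA:
        for aa_b in STANDARD_AA:
            subs = []
            if aa_a != wt_a:
                subs.append((site_a, wt_a, aa_a))
            if aa_b != wt_b:
                subs.append((site_b, wt_b, aa_b))
            variants.append(Variant(tuple(subs)))
    return Library(
        variants=variants,
        scheme="ssm_double",
        sites=sorted([site_a, site_b]),
        includes_wt=True,
    )
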