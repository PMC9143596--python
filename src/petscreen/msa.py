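"""Multiple-sequence-alignment handling, conservation scoring and site nomination.

Candidate mutation sites on the reference enzyme are nominated from an
alignment against homologous PET-degrading enzymes: positions in loop
regions facing the active site are taken as-is, while helix/sheet
positions must be poorly conserved (physicochemical conservation score
strictly below a cutoff, default 6).  Catalytic-triad residues are never
nominated.

Conservation uses the Livingstone & Barton physicochemical property set:
each amino acid is a member (or not) of 10 binary properties
(hydrophobic, polar, small, proline, tiny, aliphatic, aromatic,
positive, negative, charged).  A column scores one point for every
property whose membership status is uniform across its non-gap residues;
a column of identical residues scores the maximum, 11.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = set("-.")

#: Score for a column of identical residues (rendered "*" by viewers).
IDENTITY_SCORE = 11


def _data_path(name: str):
    return importlib.resources.files("petscreen.data").joinpath(name)


def load_property_table(path=None) -> dict[str, frozenset[str]]:
    """Load the 10-property binary membership table (property -> residue set)."""
    src = path if path is not None else _data_path("aa_properties.yaml")
    with open(src) as fh:
        raw = yaml.safe_load(fh)
    return {prop: frozenset(members) for prop, members in raw.items()}


@dataclass
class AlignedSet:
    """An alignment with a designated reference row and column->residue mapping."""

    ids: list[str]
    rows: list[str]
    ref_id: str
    #: alignment column (1-based) -> reference residue number (1-based);
    #: gap columns of the reference are absent.
    column_to_ref: dict[int, int] = field(default_factory=dict)
    ref_start: int = 1

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows are not equal length: {sorted(lengths)}")
        if self.ref_id not in self.ids:
            raise KeyError(f"reference id {self.ref_id!r} not in alignment")
        if not self.column_to_ref:
            self.column_to_ref = self._build_column_map()

    def _build_column_map(self) -> dict[int, int]:
        ref_row = self.row(self.ref_id)
        mapping: dict[int, int] = {}
        resnum = self.ref_start - 1
        for col, aa in enumerate(ref_row, start=1):
            if aa not in GAP_CHARS:
                resnum += 1
                mapping[col] = resnum
        return mapping

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def column(self, col: int) -> str:
        """Residues of 1-based alignment column ``col`` (gaps included)."""
        return "".join(row[col - 1] for row in self.rows)


def read_alignment(path, fmt: str = "fasta", ref_id: str | None = None,
                   ref_start: int = 1) -> AlignedSet:
    """Read an aligned FASTA ("fasta") or Clustal ("clustal") file.

    ``ref_id`` defaults to the first record.  Records of unequal length
    raise a ``ValueError``.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    if fmt == "fasta":
        # AlignIO rejects ragged FASTA with an opaque message; read records
        # ourselves so the error names the offending length.
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        lengths = {len(r.seq) for r in records}
        if len(lengths) > 1:
            raise ValueError(
                f"aligned FASTA records have unequal lengths {sorted(lengths)}"
            )
    else:
        records = list(AlignIO.read(str(path), "clustal"))
    ids = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return AlignedSet(ids=ids, rows=rows, ref_id=ref_id or ids[0],
                      ref_start=ref_start)


def write_alignment(aln: AlignedSet, path, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    if fmt == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "clustal":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "clustal")
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")


def pairwise_identity(aln: AlignedSet, id_a: str, id_b: str) -> float:
    """Percent identity between two aligned rows.

    Numerator: columns where both rows carry the same non-gap residue.
    Denominator: columns where at least one row is non-gap (so shared gap
    columns are ignored).  Returns a value in [0, 100].
    """
    row_a, row_b = aln.row(id_a), aln.row(id_b)
    same = total = 0
    for a, b in zip(row_a, row_b):
        a_gap, b_gap = a in GAP_CHARS, b in GAP_CHARS
        if a_gap and b_gap:
            continue
        total += 1
        if not a_gap and not b_gap and a == b:
            same += 1
    if total == 0:
        raise ValueError("both rows are all gaps")
    return 100.0 * same / total


def conservation_score(residues: Iterable[str],
                       table: Mapping[str, frozenset[str]]) -> int:
    """Physicochemical conservation score of one column (gaps pre-removed)."""
    residues = [r for r in residues if r not in GAP_CHARS]
    if not residues:
        return 0
    if len(set(residues)) == 1:
        return IDENTITY_SCORE
    score = 0
    for members in table.values():
        status = {r in members for r in residues}
        if len(status) == 1:
            score += 1
    return score


def column_conservation(
    aln: AlignedSet,
    table: Mapping[str, frozenset[str]] | None = None,
    gap_flag_fraction: float = 0.5,
) -> tuple[list[int], list[bool]]:
    """Per-column conservation scores plus low-confidence flags.

    Gaps are skipped when scoring; columns with more than
    ``gap_flag_fraction`` gaps (or only gaps, which score 0) are flagged
    low-confidence.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    if table is None:
        table = load_property_table()
    scores: list[int] = []
    flags: list[bool] = []
    n = len(aln.rows)
    for col in range(1, aln.n_columns + 1):
        column = aln.column(col)
        n_gaps = sum(1 for c in column if c in GAP_CHARS)
        scores.append(conservation_score(column, table))
        flags.append(n_gaps > gap_flag_fraction * n)
    return scores, flags


@dataclass(frozen=True)
class SiteAnnotation:
    """Per-reference-residue annotation used for nomination."""

    residue_number: int
    amino_acid: str
    region: str  # "loop" | "non-loop"
    conservation: int
    catalytic: bool = False
    near_active_site: bool = False
    nominated: bool = False
    override: bool = False

    def __post_init__(self) -> None:
        if self.region not in ("loop", "non-loop"):
            raise ValueError(f"region must be loop|non-loop, got {self.region!r}")
        if not 0 <= self.conservation <= IDENTITY_SCORE:
            raise ValueError(f"conservation {self.conservation} outside [0, 11]")
        if self.catalytic and self.nominated:
            raise ValueError("catalytic sites can never be nominated")


def nominate_sites(
    annotations: Sequence[SiteAnnotation],
    score_cutoff: int = 6,
    overrides: Iterable[int] = (),
) -> list[SiteAnnotation]:
    """Apply the nomination rule and return annotations with flags set.

    A site is nominated when it is (a) a loop residue marked near the
    active site, or (b) a non-loop residue with conservation strictly
    below ``score_cutoff``, or (c) listed in ``overrides`` (sites kept
    for validation against prior mutagenesis reports despite their
    score).  Catalytic sites are excluded unconditionally; an override
    naming one is an error.
    """
    overrides = set(overrides)
    catalytic = {a.residue_number for a in annotations if a.catalytic}
    bad = overrides & catalytic
    if bad:
        raise ValueError(f"overrides name catalytic residues: {sorted(bad)}")
    out = []
    for ann in annotations:
        if ann.catalytic:
            out.append(replace(ann, nominated=False, override=False))
            continue
        is_override = ann.residue_number in overrides
        nominated = (
            is_override
            or (ann.region == "loop" and ann.near_active_site)
            or (ann.region == "non-loop" and ann.conservation < score_cutoff)
        )
        out.append(replace(ann, nominated=nominated, override=is_override))
    return out


def annotations_from_config(
    config: Sequence[Mapping], aln: AlignedSet,
    table: Mapping[str, frozenset[str]] | None = None,
) -> list[SiteAnnotation]:
    """Build annotations from a site config (list of dicts) plus the alignment.

    Each config entry carries ``residue_number``, ``region``, and
    optional ``catalytic`` / ``near_active_site`` flags; amino acid and
    conservation come from the alignment's reference row.
    """
    scores, _ = column_conservation(aln, table)
    ref_row = aln.row(aln.ref_id)
    res_to_col = {res: col for col, res in aln.column_to_ref.items()}
    out = []
    for entry in config:
        res = int(entry["residue_number"])
        if res not in res_to_col:
            raise KeyError(f"residue {res} not present in reference row")
        col = res_to_col[res]
        out.append(
            SiteAnnotation(
                residue_number=res,
                amino_acid=ref_row[col - 1],
                region=entry["region"],
                conservation=scores[col - 1],
                catalytic=bool(entry.get("catalytic", False)),
                near_active_site=bool(entry.get("near_active_site", False)),
            )
        )
    return out


def annotations_to_frame(annotations: Sequence[SiteAnnotation]):
    import pandas as pd

    return pd.DataFrame([vars(a) for a in annotations])
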