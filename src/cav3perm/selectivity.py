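"""Selectivity-filter classification from aligned P-loop channel sequences.

Four sequence features determine how a four-domain channel treats sodium
versus calcium:

* the selectivity-filter ring, one residue per domain (DEKA in Nav1
  channels, DEEA in Nav2, all-acidic EE(D)DD or EEEE in calcium channels);
* the aspartate immediately C-terminal to the Domain II ring glutamate
  (the "+1" aspartate), whose neutralization confers sodium permeability;
* the turret residue of the Domain II S5-P1 loop (exon-12 region in
  invertebrate Cav3 channels): a lysine there can salt-bridge to and
  neutralize the +1 aspartate;
* cysteine inventories per extracellular loop (disulfide scaffolding;
  counted only - pairing requires structure and is out of scope).

Input is a curated alignment plus an explicit role map: this module never
aligns sequences itself, because silently divergent alignments would shift
role columns.  Coordinates are 1-based alignment columns; loop intervals
are closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "ChannelRecord",
    "FilterAnnotation",
    "REQUIRED_ROLES",
    "CLASSIFICATION_CATEGORIES",
    "extract_filter_ring",
    "classify_selectivity",
    "count_cysteines",
    "annotate",
    "read_channel_records",
    "example_channel_set",
    "annotation_table",
]

GAP = "-"
REQUIRED_ROLES = (
    "ring_DI",
    "ring_DII",
    "ring_DIII",
    "ring_DIV",
    "dII_plus1",
    "turret_exon12",
)
CLASSIFICATION_CATEGORIES = (
    "calcium-selective",
    "sodium-permeable",
    "sodium-selective",
    "non-selective",
    "unclassified",
)
_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
_ACIDIC = {"D", "E"}


@dataclass
class ChannelRecord:
    """One aligned channel sequence plus its role map and loop intervals."""

    id: str
    aligned_sequence: str
    role_map: dict[str, int]  # role -> 1-based alignment column
    loop_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        length = len(self.aligned_sequence)
        missing = [r for r in REQUIRED_ROLES if r not in self.role_map]
        if missing:
            raise ValueError(f"{self.id}: missing roles {missing}")
        for role, col in self.role_map.items():
            if not 1 <= col <= length:
                raise ValueError(f"{self.id}: role {role} column {col} outside 1..{length}")
        intervals = sorted(self.loop_intervals.values())
        for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
            if a2 <= b1:
                raise ValueError(f"{self.id}: overlapping loop intervals")

    def residue_at(self, column: int) -> str:
        """Residue at a 1-based alignment column, upper-cased."""
        if not 1 <= column <= len(self.aligned_sequence):
            raise IndexError(f"column {column} outside alignment of length {len(self.aligned_sequence)}")
        return self.aligned_sequence[column - 1].upper()


@dataclass
class FilterAnnotation:
    """Per-channel selectivity determinants and their classification."""

    channel_id: str
    ring: tuple[str, str, str, str]
    dII_plus1: str
    turret_residue: str
    classification: str = "unclassified"
    cys_counts: dict[str, int] = field(default_factory=dict)
    reason: str = ""

    @property
    def category(self) -> str:
        """Coarse label without the mechanistic qualifier in parentheses."""
        return self.classification.split(" (")[0]


def extract_filter_ring(record: ChannelRecord) -> FilterAnnotation:
    """Read the ring, +1 and turret residues at the mapped columns.

    A gap at any required role yields an unclassified annotation carrying
    the reason rather than an exception: curated alignments legitimately
    leave roles unresolved for distant homologs.
    """
    residues = {role: record.residue_at(record.role_map[role]) for role in REQUIRED_ROLES}
    gapped = [role for role, res in residues.items() if res == GAP]
    ring = tuple(residues[f"ring_D{d}"] for d in ("I", "II", "III", "IV"))
    ann = FilterAnnotation(
        channel_id=record.id,
        ring=ring,  # type: ignore[arg-type]
        dII_plus1=residues["dII_plus1"],
        turret_residue=residues["turret_exon12"],
    )
    if gapped:
        ann.classification = "unclassified"
        ann.reason = f"gap at role: {', '.join(sorted(gapped))}"
    return ann


def classify_selectivity(ring, dII_plus1: str, turret_residue: str) -> str:
    """Classification label from the three sequence determinants.

    Precedence: (1) a ring lysine in Domain II or III marks a Nav1-type
    sodium-selective filter; (2) the DEEA ring marks the non-selective
    Nav2 type; (3) an all-acidic ring with the +1 aspartate is
    calcium-selective unless a turret lysine neutralizes that aspartate;
    (4) an all-acidic ring with asparagine at +1 (EN instead of ED) is
    sodium-permeable by direct neutralization.  Anything else is
    unclassified.
    """
    ring = tuple(r.upper() for r in ring)
    dII_plus1 = dII_plus1.upper()
    turret_residue = turret_residue.upper()
    for res in (*ring, dII_plus1, turret_residue):
        if res not in _STANDARD_RESIDUES:
            raise ValueError(f"non-standard residue {res!r}")
    if len(ring) != 4:
        raise ValueError("ring must have exactly 4 residues")

    if ring[1] == "K" or ring[2] == "K":
        return "sodium-selective (Nav1-like)"
    if ring == ("D", "E", "E", "A"):
        return "non-selective (Nav2-like)"
    if all(r in _ACIDIC for r in ring):
        if dII_plus1 == "D":
            if turret_residue == "K":
                return "sodium-permeable (turret-lysine)"
            return "calcium-selective"
        if dII_plus1 == "N":
            return "sodium-permeable (EN-type)"
    return "unclassified"


def count_cysteines(record: ChannelRecord) -> dict[str, int]:
    """Cysteines per loop interval (closed, 1-based); gaps ignored."""
    counts = {}
    length = len(record.aligned_sequence)
    for loop, (start, end) in record.loop_intervals.items():
        if not (1 <= start <= end <= length):
            raise IndexError(f"{record.id}: loop {loop} interval ({start}, {end}) out of range")
        segment = record.aligned_sequence[start - 1 : end].upper()
        counts[loop] = segment.count("C")
    return counts


def annotate(record: ChannelRecord) -> FilterAnnotation:
    """Full annotation: residues, classification and cysteine counts."""
    ann = extract_filter_ring(record)
    ann.cys_counts = count_cysteines(record)
    if not ann.reason:
        ann.classification = classify_selectivity(ann.ring, ann.dII_plus1, ann.turret_residue)
    return ann


# --------------------------------------------------------------------- I/O


def _load_sidecar(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_channel_records(fasta_path: str | Path, roles_path: str | Path) -> list[ChannelRecord]:
    """Aligned FASTA plus JSON/YAML sidecar -> channel records.

    The sidecar holds ``roles`` (role -> 1-based column) and ``loops``
    (name -> [start, end]), applied to every record; ``per_record`` may
    override either for individual sequence ids.
    """
    sidecar = _load_sidecar(roles_path)
    roles = {k: int(v) for k, v in sidecar.get("roles", {}).items()}
    loops = {k: (int(v[0]), int(v[1])) for k, v in sidecar.get("loops", {}).items()}
    per_record = sidecar.get("per_record", {})
    records = []
    for seq in SeqIO.parse(str(fasta_path), "fasta"):
        override = per_record.get(seq.id, {})
        rec_roles = dict(roles)
        rec_roles.update({k: int(v) for k, v in override.get("roles", {}).items()})
        rec_loops = dict(loops)
        rec_loops.update(
            {k: (int(v[0]), int(v[1])) for k, v in override.get("loops", {}).items()}
        )
        records.append(
            ChannelRecord(
                id=seq.id,
                aligned_sequence=str(seq.seq),
                role_map=rec_roles,
                loop_intervals=rec_loops,
            )
        )
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    return records


def example_channel_set() -> list[ChannelRecord]:
    """The packaged synthetic channel panel.

    A constructed (synthetic) alignment that encodes only the
    classification-relevant residues of a representative channel panel -
    human Cav3.1/3.2/3.3, Nav1.5, Cav1.3, a Nav2-type channel, the
    molluscan and nematode Cav3 exon-12 splice forms, and the two
    anthozoan Cav3 genes.  It is not real sequence data.
    """
    data = resources.files("cav3perm") / "data"
    with resources.as_file(data / "channel_panel_synthetic.fasta") as fasta, resources.as_file(
        data / "channel_panel_roles.json"
    ) as roles:
        return read_channel_records(fasta, roles)


def annotation_table(records: list[ChannelRecord]) -> pd.DataFrame:
    """One row per channel: ring, +1, turret, classification, Cys counts."""
    rows = []
    for rec in records:
        ann = annotate(rec)
        row = {
            "id": ann.channel_id,
            "ring": "".join(ann.ring),
            "dII_plus1": ann.dII_plus1,
            "turret": ann.turret_residue,
            "classification": ann.classification,
        }
        for loop, count in sorted(ann.cys_counts.items()):
            row[f"cys_{loop}"] = count
        if ann.reason:
            row["reason"] = ann.reason
        rows.append(row)
    return pd.DataFrame(rows)
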