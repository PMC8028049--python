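"""Weighted training/validation entries and their TSV round-trip format.

An entry references structures by string id; the structures themselves travel
separately (multi-frame extended XYZ with an ``id=...`` annotation per frame),
keeping the TSV diffable.  Columns::

    id  kind  structure_ids  atoms  reference  weight  partition

``kind`` is one of ``energy_difference`` (two structure ids:
distorted,equilibrium; reference in kcal/mol), ``charge`` (one structure id,
one atom index; reference in e), or ``geometry_item`` (one structure id, 2-4
atom indices selecting a distance/angle/torsion; reference in A or degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structure import Structure, read_structure_file, write_structure_file

__all__ = ["TrainingEntry", "TrainingSet", "read_trainset", "write_trainset"]

KINDS = ("energy_difference", "charge", "geometry_item")
PARTITIONS = ("train", "validation")


@dataclass
class TrainingEntry:
    id: str
    kind: str
    structure_ids: tuple[str, ...]
    reference_value: float
    weight: float = 1.0
    partition: str = "train"
    atoms: tuple[int, ...] = ()

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"entry {self.id}: unknown kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError(f"entry {self.id}: weight must be positive")
        if self.partition not in PARTITIONS:
            raise ValueError(f"entry {self.id}: unknown partition {self.partition!r}")
        if self.kind == "energy_difference" and len(self.structure_ids) != 2:
            raise ValueError(
                f"entry {self.id}: energy differences reference exactly two structures")
        if self.kind == "charge" and (len(self.structure_ids) != 1 or len(self.atoms) != 1):
            raise ValueError(f"entry {self.id}: charge entries need one structure and one atom")
        if self.kind == "geometry_item" and not 2 <= len(self.atoms) <= 4:
            raise ValueError(f"entry {self.id}: geometry items need 2-4 atom indices")


@dataclass
class TrainingSet:
    entries: list[TrainingEntry] = field(default_factory=list)
    structures: dict[str, Structure] = field(default_factory=dict)

    def validate(self) -> None:
        for e in self.entries:
            e.validate()
            if self.structures:
                for sid in e.structure_ids:
                    if sid not in self.structures:
                        raise ValueError(
                            f"entry {e.id} references missing structure {sid!r}")

    def training(self) -> list[TrainingEntry]:
        return [e for e in self.entries if e.partition == "train"]

    def validation(self) -> list[TrainingEntry]:
        return [e for e in self.entries if e.partition == "validation"]

    def save(self, entries_path, structures_path=None) -> None:
        write_trainset(self.entries, entries_path)
        if structures_path is not None:
            frames = []
            for sid, s in self.structures.items():
                f = s.copy()
                f.info["id"] = sid
                frames.append(f)
            write_structure_file(frames, structures_path)

    @classmethod
    def load(cls, entries_path, structures_path=None) -> "TrainingSet":
        entries = read_trainset(entries_path)
        structures: dict[str, Structure] = {}
        if structures_path is not None:
            for k, s in enumerate(read_structure_file(structures_path)):
                sid = str(s.info.get("id", k))
                structures[sid] = s
        ts = cls(entries, structures)
        ts.validate()
        return ts


_HEADER = "id\tkind\tstructure_ids\tatoms\treference\tweight\tpartition"


def write_trainset(entries: list[TrainingEntry], path) -> None:
    lines = [_HEADER]
    for e in entries:
        e.validate()
        lines.append("\t".join([
            e.id, e.kind, ",".join(e.structure_ids),
            ",".join(str(a) for a in e.atoms) or "-",
            f"{e.reference_value:.10g}", f"{e.weight:.10g}", e.partition,
        ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trainset(path) -> list[TrainingEntry]:
    """Read training entries; raises ``ValueError`` on schema violations
    (unknown kind, nonpositive weight, malformed rows)."""
    entries = []
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        return entries
    start = 1 if lines[0].startswith("id\t") else 0
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        tok = ln.split("\t")
        if len(tok) != 7:
            raise ValueError(f"{path}: line {lineno}: expected 7 tab-separated columns")
        atoms = () if tok[3] in ("-", "") else tuple(int(a) for a in tok[3].split(","))
        e = TrainingEntry(
            id=tok[0], kind=tok[1],
            structure_ids=tuple(x for x in tok[2].split(",") if x),
            atoms=atoms,
            reference_value=float(tok[4]), weight=float(tok[5]),
            partition=tok[6],
        )
        e.validate()
        entries.append(e)
    return entries
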