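"""Coordinate handling: PDB I/O, amide bond vectors and secondary-structure selections.

Coordinates are in Å and residue numbering is taken verbatim from the PDB
(author numbering). A :class:`Structure` holds one model; multi-model files
require an explicit model choice. Amide N–H unit vectors, the geometric
carriers of the dipolar coupling, are extracted per residue into a
:class:`BondVectorSet` expressed in the PDB frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "BondVectorSet",
    "SseElement",
    "SseDefinition",
    "StructureError",
    "load_structure",
    "write_pdb",
    "extract_nh_vectors",
    "select_sse_vectors",
    "read_sse_config",
    "write_sse_config",
]


class StructureError(ValueError):
    """Raised for unreadable files, absent models or empty selections."""


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    x: float
    y: float
    z: float

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """Atomic coordinates of a single model.

    ``(chain, resnum, atom name)`` is unique within the model; coordinates
    must be finite.
    """

    atoms: list[Atom]
    model_id: int = 1
    _index: dict[tuple[str, int, str], int] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            if not np.isfinite([a.x, a.y, a.z]).all():
                raise StructureError(f"non-finite coordinates for atom {a}")
            key = (a.chain, a.resnum, a.name)
            if key in index:
                raise StructureError(f"duplicate atom {key} in model {self.model_id}")
            index[key] = i
        object.__setattr__(self, "_index", index)

    def get_atom(self, chain: str, resnum: int, name: str) -> Atom | None:
        i = self._index.get((chain, resnum, name))
        return None if i is None else self.atoms[i]

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def residues(self, chain: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain == chain:
                seen.setdefault(a.resnum, None)
        return sorted(seen)

    def resname(self, chain: str, resnum: int) -> str | None:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum:
                return a.resname
        return None

    def coords(self, chain: str, resnum: int, name: str) -> np.ndarray:
        atom = self.get_atom(chain, resnum, name)
        if atom is None:
            raise StructureError(f"atom {name} of {chain}{resnum} not found")
        return atom.pos

    def with_atoms(self, atoms: list[Atom]) -> "Structure":
        return Structure(atoms=atoms, model_id=self.model_id)


@dataclass
class BondVectorSet:
    """Per-residue unit internuclear vectors (dimensionless, PDB frame)."""

    entries: dict[int, np.ndarray]
    source: str = "N-H"
    missing: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for res, v in self.entries.items():
            v = np.asarray(v, dtype=float)
            n = np.linalg.norm(v)
            if abs(n - 1.0) > 1e-9:
                raise StructureError(
                    f"bond vector for residue {res} has norm {n}, expected 1"
                )
            self.entries[res] = v

    def residues(self) -> list[int]:
        return sorted(self.entries)

    def as_array(self, residues=None) -> np.ndarray:
        if residues is None:
            residues = self.residues()
        return np.array([self.entries[r] for r in residues])

    def subset(self, residues) -> "BondVectorSet":
        keep = {r: self.entries[r] for r in residues if r in self.entries}
        return BondVectorSet(entries=keep, source=self.source)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, res: int) -> bool:
        return res in self.entries


@dataclass(frozen=True)
class SseElement:
    label: str
    start: int
    end: int
    kind: str  # "helix" | "strand"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise StructureError(f"element {self.label}: start > end")
        if self.kind not in ("helix", "strand"):
            raise StructureError(f"element {self.label}: kind must be helix|strand")

    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class SseDefinition:
    """Inclusive residue ranges of α-helices and β-strands; non-overlapping."""

    elements: list[SseElement]

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for e in self.elements:
            r = set(e.residues())
            if covered & r:
                raise StructureError(f"element {e.label} overlaps a previous element")
            covered |= r

    def residues(self) -> set[int]:
        out: set[int] = set()
        for e in self.elements:
            out.update(e.residues())
        return out

    def element_of(self, resnum: int) -> SseElement | None:
        for e in self.elements:
            if e.start <= resnum <= e.end:
                return e
        return None

    def __len__(self) -> int:
        return len(self.elements)


def load_structure(path, model: int = 1) -> Structure:
    """Read one model of a PDB file.

    Altloc policy: the highest-occupancy location is kept; on a tie the one
    labelled 'A' (or blank) wins. Insertion codes are rejected outright.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except FileNotFoundError:
        raise
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    wanted = None
    for m in st:
        if m.num == model:
            wanted = m
            break
    if wanted is None:
        raise StructureError(
            f"model {model} not found in {path}; present: {[m.num for m in st]}"
        )
    atoms: list[Atom] = []
    for chain in wanted:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise StructureError(
                    f"insertion code {res.seqid.icode!r} at {chain.name}"
                    f"{res.seqid.num}: insertion codes are not supported"
                )
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or _altloc_better(at, prev):
                    best[at.name] = at
            for at in best.values():
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        name=at.name,
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                    )
                )
    if not atoms:
        raise StructureError(f"model {model} of {path} contains no atoms")
    return Structure(atoms=atoms, model_id=model)


def _altloc_better(cand: gemmi.Atom, incumbent: gemmi.Atom) -> bool:
    if cand.occ != incumbent.occ:
        return cand.occ > incumbent.occ
    return _altloc_rank(cand.altloc) < _altloc_rank(incumbent.altloc)


def _altloc_rank(altloc: str) -> tuple[int, str]:
    # blank or 'A' preferred on an occupancy tie
    if altloc in ("", " ", "\x00", "A"):
        return (0, "")
    return (1, altloc)


def write_pdb(structure: Structure, path) -> None:
    """Write ATOM records (3-decimal coordinates) with MODEL/ENDMDL framing."""
    with open(path, "w") as fh:
        fh.write(f"MODEL     {structure.model_id:4d}\n")
        serial = 0
        for a in structure.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            elem = a.name.strip()[0]
            fh.write(
                f"ATOM  {serial:5d} {name:<4s} {a.resname:<3s} {a.chain:1s}"
                f"{a.resnum:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {elem:>2s}\n"
            )
        fh.write("ENDMDL\n")
        fh.write("END\n")


_AMIDE_H_NAMES = ("H", "HN")


def extract_nh_vectors(structure: Structure, chain: str) -> BondVectorSet:
    """Unit vectors (H − N)/‖H − N‖ per residue of a chain.

    Residues missing either atom are omitted and listed in ``missing``;
    prolines (no amide proton) are never included. The amide proton may be
    named ``H`` or ``HN``; the first present wins.
    """
    entries: dict[int, np.ndarray] = {}
    missing: list[int] = []
    for resnum in structure.residues(chain):
        resname = structure.resname(chain, resnum)
        if resname == "PRO":
            continue
        n_atom = structure.get_atom(chain, resnum, "N")
        h_atom = None
        for hname in _AMIDE_H_NAMES:
            h_atom = structure.get_atom(chain, resnum, hname)
            if h_atom is not None:
                break
        if n_atom is None or h_atom is None:
            missing.append(resnum)
            continue
        v = h_atom.pos - n_atom.pos
        entries[resnum] = v / np.linalg.norm(v)
    if not entries:
        raise StructureError(f"no N-H vectors extractable from chain {chain!r}")
    return BondVectorSet(entries=entries, source="N-H", missing=missing)


def select_sse_vectors(vectors: BondVectorSet, sses: SseDefinition) -> BondVectorSet:
    """Restrict a vector set to residues inside any secondary-structure element."""
    if len(sses) == 0:
        raise StructureError("empty secondary-structure definition")
    keep = sses.residues() & set(vectors.entries)
    if not keep:
        raise StructureError("no bond vectors inside the given elements")
    out = vectors.subset(sorted(keep))
    return out


def read_sse_config(path) -> SseDefinition:
    """Read elements from a plain config file: one ``label kind start end`` per line."""
    elements = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise StructureError(f"malformed SSE line: {line!r}")
            label, kind, start, end = parts
            elements.append(SseElement(label, int(start), int(end), kind))
    return SseDefinition(elements=elements)


def write_sse_config(sses: SseDefinition, path) -> None:
    with open(path, "w") as fh:
        fh.write("# label kind start end\n")
        for e in sses.elements:
            fh.write(f"{e.label} {e.kind} {e.start} {e.end}\n")
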