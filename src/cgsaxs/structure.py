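"""All-atom PDB parsing and reduction to dummy-atom (bead) models.

A protein is reduced to one scattering body per residue (one-body model) or
to a backbone body plus a side-chain body (two-body model).  Glycine and
alanine are too small to split and always contribute a single whole-residue
bead.  Beads sit at the unweighted centroid of their heavy atoms; the Cbeta
atom counts toward the backbone centroid, not the side chain.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: heavy atoms pooled into the backbone centroid (Cbeta included by convention)
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "CB", "OXT"})

#: residues represented by a single whole-residue bead under the two-body model
SINGLE_BEAD_RESIDUES = frozenset({"GLY", "ALA"})

#: generic backbone label of the two-body alphabet
BACKBONE_LABEL = "BB"


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class StructureError(ValueError):
    """Raised for invalid or unsupported molecular content."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of an all-atom model."""

    element: str
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name} has invalid position {pos}")
        object.__setattr__(self, "position", pos)
        if self.element.upper() in ("H", "D"):
            raise StructureError("hydrogens are excluded from scattering models")


@dataclass(frozen=True)
class BeadAlphabet:
    """Ordered label set of a coarse-grained representation.

    ``two`` granularity: a generic backbone label, whole-residue labels for
    alanine and glycine (marked ``*``), and 18 side-chain labels — 21 in
    total.  ``one`` granularity: 20 whole-residue amino-acid labels.
    """

    granularity: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.granularity == "one":
            if len(self.labels) != 20:
                raise StructureError("one-body alphabet must have 20 labels")
        elif self.granularity == "two":
            if len(self.labels) != 21:
                raise StructureError("two-body alphabet must have 21 labels")
        else:
            raise StructureError(f"unknown granularity {self.granularity!r}")

    @classmethod
    def one_body(cls) -> "BeadAlphabet":
        return cls("one", AMINO_ACIDS)

    @classmethod
    def two_body(cls) -> "BeadAlphabet":
        side = tuple(a for a in AMINO_ACIDS if a not in SINGLE_BEAD_RESIDUES)
        return cls("two", (BACKBONE_LABEL, "ALA*", "GLY*") + side)

    @classmethod
    def for_granularity(cls, granularity: str) -> "BeadAlphabet":
        return cls.one_body() if granularity == "one" else cls.two_body()

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class CoarseBead:
    """A dummy atom: one scattering body at the centroid of an atom group."""

    label: str
    position: np.ndarray
    residue_index: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"bead {self.label} has invalid position")
        object.__setattr__(self, "position", pos)


@dataclass
class CoarseStructure:
    """Ordered dummy-atom model of one protein chain."""

    beads: list[CoarseBead]
    granularity: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.beads) < 1:
            raise StructureError("a coarse structure needs at least one bead")
        alphabet = BeadAlphabet.for_granularity(self.granularity)
        for b in self.beads:
            if b.label not in alphabet.labels:
                raise StructureError(f"bead label {b.label!r} not in alphabet")

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def coordinates(self) -> np.ndarray:
        """(M, 3) bead positions in Angstrom."""
        return np.array([b.position for b in self.beads], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.beads]


def _validate_atom_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})")


def parse_structure(pdb_source, chain: str | None = None) -> list[AtomRecord]:
    """Read heavy atoms of one chain from PDB text.

    Parameters
    ----------
    pdb_source
        Path, file-like object, or PDB-format string.
    chain
        Chain identifier; by default the first chain holding ATOM records.

    Hydrogens, waters, HETATM records and alternate conformers other than
    altloc ``' '``/``'A'`` are dropped.
    """
    if hasattr(pdb_source, "read"):
        text = pdb_source.read()
    else:
        s = str(pdb_source)
        if "\n" in s or s.lstrip().startswith(("ATOM", "HEADER", "HETATM",
                                               "REMARK", "MODEL", "CRYST1")):
            text = s
        else:
            with open(s) as fh:
                text = fh.read()
    _validate_atom_lines(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"PDB parsing failed: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no ATOM records found")
    model = st[0]
    records: list[AtomRecord] = []
    seen_chains = []
    for ch in model:
        seen_chains.append(ch.name)
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.het_flag != "A":       # HETATM / waters
                continue
            for atom in res:
                el = atom.element.name.upper()
                if el in ("H", "D"):
                    continue
                if atom.altloc not in ("\0", "", " ", "A"):
                    continue
                records.append(AtomRecord(
                    element=el,
                    name=atom.name,
                    res_name=res.name.strip(),
                    chain_id=ch.name,
                    res_seq=res.seqid.num,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                ))
        if chain is None and records:
            break
    if not records:
        if chain is not None and chain not in seen_chains:
            raise PDBParseError(
                f"chain {chain!r} not present (chains: {seen_chains})")
        raise PDBParseError("no heavy ATOM records found in requested chain")
    return records


def _group_by_residue(atoms: Sequence[AtomRecord]):
    groups: list[tuple[tuple[str, int, str], list[AtomRecord]]] = []
    for a in atoms:
        key = (a.chain_id, a.res_seq, a.res_name)
        if groups and groups[-1][0] == key:
            groups[-1][1].append(a)
        else:
            groups.append((key, [a]))
    return groups


def _centroid(atoms: Iterable[AtomRecord]) -> np.ndarray:
    pts = np.array([a.position for a in atoms], dtype=float)
    return pts.mean(axis=0)


def coarse_grain(
    atoms: Sequence[AtomRecord],
    granularity: str,
    residue_map: Mapping[str, str] | None = None,
    source_id: str = "",
) -> CoarseStructure:
    """Reduce heavy atoms to a one-body or two-body dummy-atom model.

    Two-body: backbone bead at the unweighted centroid of the N, CA, C, O,
    CB (and OXT) atoms present; side-chain bead at the centroid of the
    remaining heavy atoms; Gly/Ala collapse to one whole-residue bead.
    One-body: one bead per residue at the centroid of all heavy atoms.
    Bead order follows residue order, backbone before side chain.

    ``residue_map`` optionally maps nonstandard residue names onto standard
    ones (e.g. ``{"MSE": "MET"}``); unknown residues raise ``StructureError``.
    """
    if granularity not in ("one", "two"):
        raise StructureError(f"unknown granularity {granularity!r}")
    residue_map = dict(residue_map or {})
    beads: list[CoarseBead] = []
    for ridx, ((_, seq, raw_name), group) in enumerate(_group_by_residue(atoms)):
        name = residue_map.get(raw_name, raw_name)
        if name not in AMINO_ACIDS:
            raise StructureError(
                f"unknown residue type {raw_name!r} at position {seq}; "
                "provide a residue_map entry or remove it")
        if not group:
            raise StructureError(f"residue {name} {seq} has no heavy atoms")
        if granularity == "one":
            beads.append(CoarseBead(name, _centroid(group), ridx))
            continue
        if name in SINGLE_BEAD_RESIDUES:
            beads.append(CoarseBead(name + "*", _centroid(group), ridx))
            continue
        backbone = [a for a in group if a.name in BACKBONE_ATOMS]
        side = [a for a in group if a.name not in BACKBONE_ATOMS]
        if not backbone:
            raise StructureError(f"residue {name} {seq} has no backbone atoms")
        beads.append(CoarseBead(BACKBONE_LABEL, _centroid(backbone), ridx))
        if side:
            beads.append(CoarseBead(name, _centroid(side), ridx))
        else:
            warnings.warn(
                f"residue {name} {seq} has no side-chain heavy atoms; "
                "emitting backbone bead only", stacklevel=2)
    return CoarseStructure(beads, granularity, source_id)


def coarse_ratio(atoms: Sequence[AtomRecord], structure: CoarseStructure) -> float:
    """Average number of heavy atoms per dummy atom, k.

    The Debye double sum over pairs shrinks by a factor k^2 relative to an
    all-atom evaluation.
    """
    return len(atoms) / len(structure)
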