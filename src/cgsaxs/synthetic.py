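"""Synthetic protein-like fixtures: structures, reference curves, decoys.

Stands in for curated training/validation/decoy data sets so that form
factor estimation and decoy-recognition experiments run without external
inputs.  Backbones are self-avoiding C-alpha walks with ideal-offset N, C,
O and C-beta atoms; side chains are compact random clusters with the heavy
atom element composition of the real amino acids.  The geometry is not
Ramachandran-valid and the side chains are not rotamers — the downstream
method consumes only heavy-atom centroids and counts, for which these
fixtures are faithful.  Reference curves come from the all-atom Debye
oracle with electron-count factors, optionally degraded with Gaussian noise
scaled to the error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .curves import ScatteringCurve
from .debye import ELEMENT_ELECTRONS, QGrid, all_atom_debye
from .scoring import ErrorModel
from .structure import AMINO_ACIDS, AtomRecord

#: side-chain heavy atoms beyond C-beta: (atom name, element)
SIDE_CHAIN_ATOMS: dict[str, list[tuple[str, str]]] = {
    "ALA": [],
    "ARG": [("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C"),
            ("NH1", "N"), ("NH2", "N")],
    "ASN": [("CG", "C"), ("OD1", "O"), ("ND2", "N")],
    "ASP": [("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "CYS": [("SG", "S")],
    "GLN": [("CG", "C"), ("CD", "C"), ("OE1", "O"), ("NE2", "N")],
    "GLU": [("CG", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
    "GLY": [],
    "HIS": [("CG", "C"), ("ND1", "N"), ("CD2", "C"), ("CE1", "C"),
            ("NE2", "N")],
    "ILE": [("CG1", "C"), ("CG2", "C"), ("CD1", "C")],
    "LEU": [("CG", "C"), ("CD1", "C"), ("CD2", "C")],
    "LYS": [("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "MET": [("CG", "C"), ("SD", "S"), ("CE", "C")],
    "PHE": [("CG", "C"), ("CD1", "C"), ("CD2", "C"), ("CE1", "C"),
            ("CE2", "C"), ("CZ", "C")],
    "PRO": [("CG", "C"), ("CD", "C")],
    "SER": [("OG", "O")],
    "THR": [("OG1", "O"), ("CG2", "C")],
    "TRP": [("CG", "C"), ("CD1", "C"), ("CD2", "C"), ("NE1", "N"),
            ("CE2", "C"), ("CE3", "C"), ("CZ2", "C"), ("CZ3", "C"),
            ("CH2", "C")],
    "TYR": [("CG", "C"), ("CD1", "C"), ("CD2", "C"), ("CE1", "C"),
            ("CE2", "C"), ("CZ", "C"), ("OH", "O")],
    "VAL": [("CG1", "C"), ("CG2", "C")],
}

#: default amino-acid composition weights (approximate natural frequencies,
#: percent); gives about 7.8 heavy atoms per residue on average
NATURAL_COMPOSITION: dict[str, float] = {
    "ALA": 8.3, "ARG": 5.5, "ASN": 4.1, "ASP": 5.5, "CYS": 1.4,
    "GLN": 3.9, "GLU": 6.8, "GLY": 7.1, "HIS": 2.3, "ILE": 6.0,
    "LEU": 9.7, "LYS": 5.8, "MET": 2.4, "PHE": 3.9, "PRO": 4.7,
    "SER": 6.6, "THR": 5.3, "TRP": 1.1, "TYR": 2.9, "VAL": 6.9,
}

CA_STEP = 3.8          # consecutive C-alpha distance, Angstrom
CLEARANCE = 4.0        # minimum non-neighbor C-alpha distance, Angstrom


class FixtureError(RuntimeError):
    """Raised when fixture generation fails."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic protein fixture."""

    n_residues: int = 40
    composition: dict[str, float] | None = None
    seed: int = 0
    noise_level: float = 0.0       # reference-curve noise in multiples of sigma_q
    n_decoys: int = 100
    decoy_scale: float = 4.0       # maximum hinge-perturbation scale, Angstrom-like

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise FixtureError("need at least 2 residues")
        if self.noise_level < 0:
            raise FixtureError("noise level must be nonnegative")

    def weights(self) -> np.ndarray:
        comp = self.composition or NATURAL_COMPOSITION
        w = np.array([comp.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
        if w.sum() <= 0:
            raise FixtureError("empty composition")
        return w / w.sum()


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _ca_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    for _ in range(40):            # restarts
        pts = [np.zeros(3)]
        ok = True
        for _i in range(1, n):
            placed = False
            for _try in range(300):
                cand = pts[-1] + CA_STEP * _random_unit(rng)
                if len(pts) < 2:
                    placed = True
                elif np.min(np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)) >= CLEARANCE:
                    placed = True
                if placed:
                    pts.append(cand)
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise FixtureError(
        "self-avoiding walk failed; increase the clearance box or reduce "
        "the residue count")


def _local_frame(ca: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if i + 1 < len(ca):
        u = _unit(ca[i + 1] - ca[i])
    else:
        u = _unit(ca[i] - ca[i - 1])
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    v = _unit(np.cross(u, ref))
    w = np.cross(u, v)
    return u, v, w


def generate_structure(spec: FixtureSpec) -> list[AtomRecord]:
    """Deterministic protein-like all-atom model from a fixture spec."""
    rng = np.random.default_rng(spec.seed)
    seq = rng.choice(len(AMINO_ACIDS), size=spec.n_residues, p=spec.weights())
    ca = _ca_walk(spec.n_residues, rng)
    atoms: list[AtomRecord] = []
    for i in range(spec.n_residues):
        res = AMINO_ACIDS[int(seq[i])]
        u, v, w = _local_frame(ca, i)
        def place(offsets):
            return ca[i] + offsets[0] * u + offsets[1] * v + offsets[2] * w
        def add(name, element, pos):
            atoms.append(AtomRecord(element, name, res, "A", i + 1, pos))
        add("N", "N", place((-0.60, 1.33, 0.0)))
        add("CA", "C", ca[i])
        c_pos = place((0.88, -1.24, 0.0))
        add("C", "C", c_pos)
        add("O", "O", c_pos + (-0.67 * v + 1.03 * w))
        if res != "GLY":
            cb = place((-0.55, -0.77, 1.21))
            add("CB", "C", cb)
            for name, element in SIDE_CHAIN_ATOMS[res]:
                d = rng.uniform(1.5, 3.5)
                add(name, element, cb + d * _random_unit(rng))
    return atoms


def generate_reference(
    atoms: list[AtomRecord],
    grid: QGrid | None = None,
    model: ErrorModel | None = None,
    noise_level: float = 0.0,
    seed: int = 0,
) -> ScatteringCurve:
    """All-atom Debye reference curve with simulated experimental noise.

    Gaussian noise with standard deviation ``noise_level * sigma_q`` is
    added to the noiseless oracle intensity and clipped at zero; the sigma
    column always reports the error model of the noiseless intensity.
    """
    grid = grid or QGrid()
    model = model or ErrorModel()
    clean = all_atom_debye(atoms, ELEMENT_ELECTRONS, grid)
    sigma = model.sigma(clean.q, clean.intensity)
    intensity = clean.intensity
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(
            intensity + rng.normal(scale=noise_level * sigma), 0.0, None)
    return ScatteringCurve(grid.q, intensity, sigma)


def _hinge_perturb(coords: np.ndarray, res_index: np.ndarray, scale: float,
                   rng: np.random.Generator, n_moves: int = 4) -> np.ndarray:
    """Rigid rotations of random chain suffixes about C-alpha pivots."""
    out = coords.copy()
    n_res = int(res_index.max())
    for _ in range(n_moves):
        pivot_res = int(rng.integers(1, n_res))
        mask = res_index > pivot_res
        if not mask.any():
            continue
        pivot_atoms = out[(res_index == pivot_res)]
        center = pivot_atoms.mean(axis=0)
        angle = rng.uniform(-1.0, 1.0) * 0.045 * scale
        axis = _random_unit(rng)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        out[mask] = (out[mask] - center) @ R.T + center
    return out


def generate_decoys(atoms: list[AtomRecord], spec: FixtureSpec) -> list[list[AtomRecord]]:
    """Perturbed copies of a native structure with increasing deformation.

    Decoy d (d = 1..n) is produced by seeded random hinge rotations whose
    magnitude grows linearly up to ``spec.decoy_scale``, giving a ladder of
    RMSD-to-native values.  The native itself is never returned.
    """
    rng = np.random.default_rng(spec.seed + 1)
    coords = np.array([a.position for a in atoms])
    res_index = np.array([a.res_seq for a in atoms])
    decoys = []
    for d in range(1, spec.n_decoys + 1):
        scale = spec.decoy_scale * d / spec.n_decoys
        new = _hinge_perturb(coords, res_index, scale, rng)
        decoys.append([
            AtomRecord(a.element, a.name, a.res_name, a.chain_id, a.res_seq, p)
            for a, p in zip(atoms, new)
        ])
    return decoys


def rmsd(atoms_a: list[AtomRecord], atoms_b: list[AtomRecord]) -> float:
    """Coordinate RMSD between two conformations of the same atom list."""
    pa = np.array([a.position for a in atoms_a])
    pb = np.array([a.position for a in atoms_b])
    if pa.shape != pb.shape:
        raise FixtureError("atom lists differ in length")
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def generate_table(alphabet, grid: QGrid | None = None, seed: int = 0):
    """Smooth synthetic form-factor table for parameter-recovery studies.

    Each bead type gets F(q) = A * exp(-(q R)^2 / 2): an electron-count-like
    amplitude A in [15, 35] with a Gaussian amplitude decay of radius
    R in [1.2, 2.2] Angstrom, the size scale of backbone and side-chain
    moieties.  Values stay well inside the sampling box [0, 40].
    """
    from .debye import FormFactorTable
    grid = grid or QGrid()
    rng = np.random.default_rng(seed)
    L = len(alphabet.labels)
    amp = rng.uniform(15.0, 35.0, size=L)
    radius = rng.uniform(1.2, 2.2, size=L)
    q = grid.q
    values = amp[:, None] * np.exp(-0.5 * (q[None, :] * radius[:, None]) ** 2)
    return FormFactorTable(alphabet, grid, values)


def stratified_compositions(n: int, boost: float = 0.5) -> list[dict[str, float]]:
    """Composition weights for a training set with designed contrast.

    Set member i mixes the natural background with a ``boost`` fraction of
    a single amino-acid type (cycling through the 20 types), so the
    per-q-bin estimation problem is well conditioned even for small
    training sets; large curated sets achieve the same contrast simply by
    being numerous and diverse.
    """
    base = np.array([NATURAL_COMPOSITION[a] for a in AMINO_ACIDS])
    base = base / base.sum()
    comps = []
    for i in range(n):
        w = (1.0 - boost) * base.copy()
        w[i % len(AMINO_ACIDS)] += boost
        comps.append({a: float(x) for a, x in zip(AMINO_ACIDS, w)})
    return comps


def atoms_to_pdb(atoms: list[AtomRecord], path=None) -> str:
    """Write atoms as a standard single-chain PDB file (or return the text)."""
    st = gemmi.Structure()
    st.name = "fixture"
    model = gemmi.Model("1")
    chain = gemmi.Chain(atoms[0].chain_id if atoms else "A")
    current = None
    res = None
    for a in atoms:
        key = (a.res_seq, a.res_name)
        if key != current:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            res.het_flag = "A"
            chain.add_residue(res)
            res = chain[-1]
            current = key
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.position)
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
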