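"""Minimal structure comparison: PDB reading, helix selection, Kabsch RMSD.

Supports the modelling-side sanity check of the toolkit: superpose two
PAH-domain structures over their four-helix bundles and report the
backbone RMSD.  "Backbone" defaults to N, CA, C; pass
``atoms=("N", "CA", "C", "O")`` to include carbonyl oxygens.  Reading
goes through gemmi (PDB and, where gemmi supports it, mmCIF); only one
model is kept per read — NMR ensembles are compared via their first
members unless another model index is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

import gemmi

__all__ = [
    "Atom",
    "StructureModel",
    "HelixSegment",
    "read_structure",
    "write_structure",
    "superpose_rmsd",
    "pair_helix_atoms",
    "compare_pah1_structures",
    "make_synthetic_bundle",
    "transform_model",
]

BACKBONE_ATOMS = ("N", "CA", "C")

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AA1 = {v: k for k, v in _AA3.items()}


class Atom(NamedTuple):
    chain: str
    resnum: int
    resname: str
    name: str
    x: float
    y: float
    z: float


@dataclass
class StructureModel:
    """Coordinates of a single model of a structure file."""

    atoms: list[Atom]
    model_index: int = 1
    label: str = ""

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def select(self, chain: str, resnum: int, names: Sequence[str]) -> list[Atom]:
        wanted = list(names)
        found = {a.name: a for a in self.atoms if a.chain == chain and a.resnum == resnum}
        return [found[n] for n in wanted if n in found]

    def residue_name(self, chain: str, resnum: int) -> Optional[str]:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum:
                return a.resname
        return None


@dataclass(frozen=True)
class HelixSegment:
    chain: str
    start: int  # author numbering, inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("helix start must be <= end")

    def __len__(self) -> int:
        return self.end - self.start + 1


def read_structure(path, model: int = 1) -> tuple[StructureModel, list[HelixSegment]]:
    """Read one model of a PDB/mmCIF file plus its HELIX annotations.

    ``model`` is the 1-based index into the file's models ("first
    member" of an NMR ensemble = 1).  Atoms with blank or 'A' altloc are
    kept; alternates are discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    if not 1 <= model <= len(st):
        raise ValueError(f"{path}: model {model} not present (file has {len(st)})")
    gm = st[model - 1]
    atoms: list[Atom] = []
    for chain in gm:
        for res in chain:
            for at in res:
                if at.altloc not in ("\x00", "", "A"):
                    continue
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
        raise ValueError(f"{path}: model {model} has no coordinates")
    helices = [
        HelixSegment(
            chain=h.start.chain_name,
            start=h.start.res_id.seqid.num,
            end=h.end.res_id.seqid.num,
        )
        for h in st.helices
    ]
    return StructureModel(atoms=atoms, model_index=model, label=path.stem), helices


def write_structure(model: StructureModel, helices: Sequence[HelixSegment], path) -> Path:
    """Write a model (with HELIX records) as PDB via gemmi."""
    st = gemmi.Structure()
    st.name = model.label or "sidmap"
    gm = gemmi.Model(1)
    # gemmi's add_* methods copy, so each container is filled before insertion
    grouped: dict[str, dict[int, list[Atom]]] = {}
    for a in model.atoms:
        grouped.setdefault(a.chain, {}).setdefault(a.resnum, []).append(a)
    for chain_name, residues in grouped.items():
        ch = gemmi.Chain(chain_name)
        for resnum, atoms in residues.items():
            res = gemmi.Residue()
            res.name = atoms[0].resname
            res.seqid = gemmi.SeqId(resnum, " ")
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.pos = gemmi.Position(a.x, a.y, a.z)
                at.element = gemmi.Element(a.name[:1])
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    for seg in helices:
        h = gemmi.Helix()
        start_name = model.residue_name(seg.chain, seg.start) or "ALA"
        end_name = model.residue_name(seg.chain, seg.end) or "ALA"
        h.start = gemmi.AtomAddress(seg.chain, gemmi.SeqId(seg.start, " "), start_name, "CA")
        h.end = gemmi.AtomAddress(seg.chain, gemmi.SeqId(seg.end, " "), end_name, "CA")
        h.pdb_helix_class = 1
        h.length = len(seg)
        st.helices.append(h)
    st.setup_entities()
    path = Path(path)
    path.write_text(st.make_pdb_string())
    return path


def _segment_sequence(model: StructureModel, seg: HelixSegment) -> str:
    out = []
    for resnum in range(seg.start, seg.end + 1):
        name = model.residue_name(seg.chain, resnum)
        out.append(_AA1.get(name or "", "X"))
    return "".join(out)


def _align_offsets(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Residue-offset pairs from a global alignment of two segment sequences."""
    if seq_a == seq_b or len(seq_a) == len(seq_b):
        n = min(len(seq_a), len(seq_b))
        return [(k, k) for k in range(n)]
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def pair_helix_atoms(
    a: StructureModel,
    b: StructureModel,
    segments_a: Sequence[HelixSegment],
    segments_b: Sequence[HelixSegment],
    atoms: Sequence[str] = BACKBONE_ATOMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired coordinate arrays over corresponding helix segments.

    Segments correspond by order; residues within a segment pair are
    matched by sequence alignment of the segment sequences (plain offset
    when the segments have equal length); atoms by name.  Positions
    where either structure lacks one of the requested atoms are skipped.
    """
    if len(segments_a) != len(segments_b):
        raise ValueError(
            f"segment count mismatch: {len(segments_a)} vs {len(segments_b)}"
        )
    P: list[Atom] = []
    Q: list[Atom] = []
    for sa, sb in zip(segments_a, segments_b):
        for ka, kb in _align_offsets(_segment_sequence(a, sa), _segment_sequence(b, sb)):
            at_a = a.select(sa.chain, sa.start + ka, atoms)
            at_b = b.select(sb.chain, sb.start + kb, atoms)
            if len(at_a) == len(atoms) and len(at_b) == len(atoms):
                P.extend(at_a)
                Q.extend(at_b)
    if len(P) != len(Q):
        raise ValueError("selection yields unequal atom counts")
    to_xyz = lambda ats: np.array([[t.x, t.y, t.z] for t in ats], dtype=float)
    return to_xyz(P), to_xyz(Q)


def superpose_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after least-squares rigid (Kabsch) superposition of paired points."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 paired atoms")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    _, rssd = Rotation.align_vectors(Pc, Qc)
    return float(rssd / np.sqrt(P.shape[0]))


def compare_pah1_structures(
    path_a,
    path_b,
    atoms: Sequence[str] = BACKBONE_ATOMS,
    model: int = 1,
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
) -> dict:
    """Backbone RMSD between two PAH-domain structures over their helices.

    Reads the requested model of each file (default: the first member
    of the ensemble), takes the HELIX records of the selected chain (by
    default the first chain that has any), pairs the segments in order,
    superposes and reports.  Intended for e.g. the PAH1:Sap25 (2RMS)
    versus PAH1:REST (2CZY) comparison once the user has downloaded the
    two entries.
    """
    ma, ha = read_structure(path_a, model=model)
    mb, hb = read_structure(path_b, model=model)

    def chain_helices(hs, chain):
        if chain is None:
            chain = hs[0].chain if hs else None
        return [h for h in hs if h.chain == chain], chain

    ha, ca = chain_helices(ha, chain_a)
    hb, cb = chain_helices(hb, chain_b)
    if not ha or not hb:
        raise ValueError("no HELIX records found for the selected chains")
    n = min(len(ha), len(hb))
    P, Q = pair_helix_atoms(ma, mb, ha[:n], hb[:n], atoms=atoms)
    rmsd = superpose_rmsd(P, Q)
    return {
        "rmsd": rmsd,
        "n_atoms": int(P.shape[0]),
        "n_helices": n,
        "atoms": tuple(atoms),
        "chains": (ca, cb),
    }


def transform_model(model: StructureModel, rotation: np.ndarray, translation: np.ndarray) -> StructureModel:
    """Apply a rigid transform x → Rx + t to every atom."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    xyz = model.coords() @ R.T + t
    atoms = [
        Atom(a.chain, a.resnum, a.resname, a.name, *map(float, p))
        for a, p in zip(model.atoms, xyz)
    ]
    return StructureModel(atoms=atoms, model_index=model.model_index, label=model.label)


# --- synthetic four-helix bundle ------------------------------------------

# idealised alpha-helix backbone geometry (per-residue rise 1.5 A,
# 100 deg/residue); good enough for superposition tests, not stereochemistry
_HELIX_RADII = {"N": 1.6, "CA": 2.3, "C": 1.7}
_HELIX_PHASE = {"N": -28.0, "CA": 0.0, "C": 26.0}
_HELIX_Z = {"N": -0.9, "CA": 0.0, "C": 0.6}


def _ideal_helix(length: int, origin: np.ndarray, direction_z: float = 1.0) -> list[dict]:
    residues = []
    for i in range(length):
        res = {}
        for name in ("N", "CA", "C"):
            ang = np.deg2rad(100.0 * i + _HELIX_PHASE[name])
            res[name] = origin + np.array(
                [
                    _HELIX_RADII[name] * np.cos(ang),
                    _HELIX_RADII[name] * np.sin(ang),
                    direction_z * (1.5 * i + _HELIX_Z[name]),
                ]
            )
        residues.append(res)
    return residues


def make_synthetic_bundle(
    seed: int = 0,
    n_helices: int = 4,
    helix_length: int = 12,
    spacing: float = 10.0,
    noise: float = 0.0,
) -> tuple[StructureModel, list[HelixSegment]]:
    """An idealised antiparallel helix bundle with optional coordinate noise.

    Synthetic stand-in for a PAH-like four-helix bundle: helices sit on
    a square of side ``spacing`` with alternating direction, chain A,
    sequential author numbering with a 3-residue gap between helices.
    ``noise`` adds isotropic Gaussian displacement (Å) to every atom.
    """
    rng = np.random.default_rng(seed)
    corners = [(0.0, 0.0), (spacing, 0.0), (spacing, spacing), (0.0, spacing)]
    seq = "ADLEKRLAQIES" * 4  # arbitrary mixed sequence
    atoms: list[Atom] = []
    segments: list[HelixSegment] = []
    resnum = 1
    for k in range(n_helices):
        cx, cy = corners[k % 4]
        origin = np.array([cx, cy, 0.0])
        start = resnum
        for i, res in enumerate(_ideal_helix(helix_length, origin, direction_z=(-1.0) ** k)):
            resname = _AA3[seq[(resnum - 1) % len(seq)]]
            for name, pos in res.items():
                p = pos + (rng.normal(0.0, noise, size=3) if noise > 0 else 0.0)
                atoms.append(Atom("A", resnum, resname, name, *map(float, p)))
            resnum += 1
        segments.append(HelixSegment(chain="A", start=start, end=resnum - 1))
        resnum += 3  # loop gap
    return StructureModel(atoms=atoms, model_index=1, label=f"synthetic-bundle-{seed}"), segments
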