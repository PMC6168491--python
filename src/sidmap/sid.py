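"""Sequence-based discovery of candidate Sin3-interaction domains (SIDs).

A SID is a short amphipathic helix that docks hydrophobic side chains
into the cleft of a Sin3A PAH four-helix bundle.  Candidates are scored
on an ideal-helix geometry (100° per residue, 3.6 residues/turn) by

* the Eisenberg hydrophobic moment μH of each window,
* whether the hydrophobic residues cluster on one helical face
  (minimal covering arc on the wheel),
* a lock-and-key motif — a pair of short hydrophobics (A/G/S/C) at
  offsets i and i+3 followed by a pair of long ones (L/I/V/M/F) at
  i+4 and i+7, the Tet1 A893/A896 + L897/L900 arrangement,
* column conservation of a supplied multiple alignment.

The combined score ranks all windows of a sliding scan; it replaces the
external secondary-structure predictors sometimes used for this task
with moment-based helicity scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EISENBERG",
    "SequenceWindow",
    "Face",
    "SIDWindowScore",
    "wheel_angles",
    "minimal_covering_arc",
    "hydrophobic_moment",
    "hydrophobic_face",
    "sid_motif_match",
    "column_conservation",
    "scan_sid",
    "read_fasta",
    "read_alignment",
    "TET1_SID_FIXTURE",
]

# Eisenberg consensus hydrophobicity scale (normalised: mean 0 over the
# 20 amino acids). Pluggable: every scorer accepts any {letter: value} map.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "K": -1.50, "L": 1.06, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

SMALL_HYDROPHOBIC = set("AGSC")
LARGE_HYDROPHOBIC = set("LIVMF")

DEGREES_PER_RESIDUE = 100.0  # ideal alpha helix, 3.6 residues per turn

_VALID = set(EISENBERG) | {"X"}


@dataclass(frozen=True)
class SequenceWindow:
    """A contiguous stretch of a parent sequence in parent numbering.

    ``start`` is the 1-based parent residue number of the first window
    residue, so window offset ``k`` corresponds to parent residue
    ``start + k``.
    """

    parent_id: str
    start: int
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty window")
        if self.start < 1:
            raise ValueError("start must be >= 1")
        bad = set(self.residues.upper()) - _VALID
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_number(self, offset: int) -> int:
        return self.start + offset


@dataclass(frozen=True)
class Face:
    """Hydrophobic-face call for a window."""

    residues: tuple[int, ...]  # parent residue numbers on the face
    arc: Optional[float]  # minimal covering arc of their wheel angles, degrees
    coherent: bool  # arc within the allowed maximum


@dataclass
class SIDWindowScore:
    window: SequenceWindow
    mu_h: float
    face: tuple[int, ...]
    face_arc: Optional[float]
    motif: bool
    motif_anchor: Optional[int]
    conservation: float
    combined: float


def wheel_angles(window: SequenceWindow) -> np.ndarray:
    """Helical-wheel angle of each residue: (100° × offset) mod 360."""
    return np.mod(DEGREES_PER_RESIDUE * np.arange(len(window)), 360.0)


def minimal_covering_arc(angles: Sequence[float]) -> float:
    """Smallest arc (degrees) containing all the given wheel angles.

    Computed as 360 minus the largest circular gap between consecutive
    sorted angles; 0 for a single angle.
    """
    a = np.sort(np.mod(np.asarray(angles, dtype=float), 360.0))
    if a.size == 0:
        raise ValueError("no angles")
    if a.size == 1:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return float(360.0 - gaps.max())


def _scale_values(window: SequenceWindow, scale: dict[str, float]) -> np.ndarray:
    centred_mean = float(np.mean(list(scale.values())))
    vals = np.array(
        [scale.get(r, centred_mean) for r in window.residues.upper()], dtype=float
    )
    return vals - centred_mean  # centring: moment of a centred profile


def hydrophobic_moment(window: SequenceWindow, scale: dict[str, float] | None = None) -> float:
    """Eisenberg hydrophobic moment per residue.

    |Σ_k h_k (cos θ_k, sin θ_k)| / L with θ_k the wheel angles; the
    scale is centred first, so adding a constant to every scale value
    leaves μH unchanged.  ``X`` contributes the scale mean (0 after
    centring).
    """
    h = _scale_values(window, scale or EISENBERG)
    theta = np.deg2rad(wheel_angles(window))
    vec = np.array([np.sum(h * np.cos(theta)), np.sum(h * np.sin(theta))])
    return float(np.linalg.norm(vec) / len(window))


def hydrophobic_face(
    window: SequenceWindow,
    scale: dict[str, float] | None = None,
    max_arc: float = 180.0,
) -> Face:
    """Residues with positive (centred) hydrophobicity, if they fit one face.

    The face is coherent when the minimal covering arc of the
    hydrophobic residues' wheel angles is at most ``max_arc`` degrees;
    otherwise no face is reported (but the arc is).
    """
    if len(window) < 2:
        raise ValueError("window must have at least 2 residues")
    h = _scale_values(window, scale or EISENBERG)
    offsets = np.nonzero(h > 0)[0]
    if offsets.size == 0:
        return Face(residues=(), arc=None, coherent=False)
    angles = wheel_angles(window)[offsets]
    arc = minimal_covering_arc(angles)
    if arc <= max_arc:
        return Face(
            residues=tuple(window.residue_number(int(k)) for k in offsets),
            arc=arc,
            coherent=True,
        )
    return Face(residues=(), arc=arc, coherent=False)


def sid_motif_match(window: SequenceWindow) -> tuple[bool, Optional[int]]:
    """Short/long hydrophobic pair motif: small@i, small@i+3, large@i+4, large@i+7.

    Returns ``(matched, anchor_offset)`` with the first matching offset.
    Requires a window of at least 8 residues.
    """
    seq = window.residues.upper()
    if len(seq) < 8:
        raise ValueError("window must have at least 8 residues")
    for i in range(len(seq) - 7):
        if (
            seq[i] in SMALL_HYDROPHOBIC
            and seq[i + 3] in SMALL_HYDROPHOBIC
            and seq[i + 4] in LARGE_HYDROPHOBIC
            and seq[i + 7] in LARGE_HYDROPHOBIC
        ):
            return True, i
    return False, None


def column_conservation(msa: Sequence[str]) -> np.ndarray:
    """Per-column conservation of an alignment, 1 − H/H_max in [0, 1].

    H is the Shannon entropy of the column over the 20 amino acids plus
    gap as a 21st symbol; H_max = log 21.  Identical columns score 1,
    a uniform spread over all 21 symbols scores 0.
    """
    rows = [r.upper() for r in msa]
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    ncol = len(rows[0])
    hmax = math.log(21.0)
    scores = np.empty(ncol)
    for j in range(ncol):
        col = [r[j] for r in rows]
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        entropy = float(-(p * np.log(p)).sum())
        scores[j] = 1.0 - entropy / hmax
    return scores


def _msa_column_map(gapped: str) -> list[int]:
    """Alignment column index of each ungapped residue position."""
    return [j for j, c in enumerate(gapped) if c not in "-."]


def scan_sid(
    sequence: str,
    parent_id: str = "query",
    msa: Sequence[str] | None = None,
    window_length: int = 11,
    scale: dict[str, float] | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    numbering_start: int = 1,
    max_arc: float = 180.0,
) -> list[SIDWindowScore]:
    """Slide a window over ``sequence`` and rank candidate SIDs.

    combined = w_moment · z(μH) + w_cons · mean column conservation
    + w_motif · [motif present].  If ``msa`` is given its first row must
    be the (possibly gapped) query, used to map windows onto alignment
    columns.  Returns every window, best first; ties broken by start
    position.
    """
    seq = sequence.upper().replace("-", "").replace(".", "")
    if window_length > len(seq):
        raise ValueError("window longer than sequence")
    if window_length < 8:
        raise ValueError("window_length must be >= 8 (motif span)")

    cons_cols = col_map = None
    if msa is not None:
        gapped = msa[0].upper()
        if gapped.replace("-", "").replace(".", "") != seq:
            raise ValueError("first alignment row must match the query sequence")
        cons_cols = column_conservation(msa)
        col_map = _msa_column_map(gapped)

    windows = []
    for k in range(len(seq) - window_length + 1):
        w = SequenceWindow(parent_id=parent_id, start=numbering_start + k, residues=seq[k : k + window_length])
        mu = hydrophobic_moment(w, scale)
        face = hydrophobic_face(w, scale, max_arc=max_arc)
        motif, anchor = sid_motif_match(w)
        if cons_cols is not None:
            cols = [col_map[k + off] for off in range(window_length)]
            cons = float(np.mean(cons_cols[cols]))
        else:
            cons = 0.0
        windows.append((w, mu, face, motif, anchor, cons))

    mus = np.array([t[1] for t in windows])
    sd = mus.std()
    z = (mus - mus.mean()) / sd if sd > 0 else np.zeros_like(mus)
    wm, wc, wb = weights
    scored = [
        SIDWindowScore(
            window=w,
            mu_h=mu,
            face=face.residues,
            face_arc=face.arc,
            motif=motif,
            motif_anchor=anchor,
            conservation=cons,
            combined=float(wm * zk + wc * cons + wb * (1.0 if motif else 0.0)),
        )
        for (w, mu, face, motif, anchor, cons), zk in zip(windows, z)
    ]
    scored.sort(key=lambda s: (-s.combined, s.window.start))
    return scored


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_alignment(path) -> list[tuple[str, str]]:
    """(id, gapped sequence) rows from an aligned FASTA file."""
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq)) for rec in aln]


# Stand-in for the Tet1 SID region 893–903. The real flanking residues are
# not bundled; only the functionally characterised positions (A893, I894,
# A896, L897, T898, L900, E902) are encoded, with neutral serines elsewhere.
# Synthetic fixture — do not mistake for the database sequence.
TET1_SID_FIXTURE = SequenceWindow(parent_id="Tet1-SID-fixture", start=893, residues="AISALTSLSES")
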