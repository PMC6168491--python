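"""Reading, writing and curating 2D amide peak lists.

A ¹⁵N-HSQC spectrum yields one cross peak per backbone amide (plus the
Asn/Gln NH₂ side-chain doublets, which carry no backbone information and
are removed before chemical-shift comparisons).  Two on-disk dialects are
supported:

* ``sparky`` — the Sparky ``.list`` layout: one header line, then
  whitespace-separated ``Assignment  w1  w2  [height]`` rows.  By default
  w1 is read as ¹⁵N and w2 as ¹H (the common convention for deposited
  amide lists); pass ``sparky_axis_order="h_n"`` to flip.
* ``csv`` — columns ``id,h_ppm,n_ppm[,intensity,kind]``.

ppm values are stored exactly as read; no referencing correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "Peak",
    "PeakList",
    "ExclusionReport",
    "read_peaklist",
    "write_peaklist",
    "exclude_sidechain_nh2",
    "BACKBONE_AMIDE",
    "SIDECHAIN_NH2",
    "UNKNOWN",
]

BACKBONE_AMIDE = "backbone_amide"
SIDECHAIN_NH2 = "sidechain_nh2"
UNKNOWN = "unknown"
_KINDS = (BACKBONE_AMIDE, SIDECHAIN_NH2, UNKNOWN)

# NH2 doublet signature used by the heuristic: two unannotated peaks that
# share a 15N position and both fall in the side-chain 1H window.
NH2_N_TOLERANCE = 0.2  # ppm, max 15N separation within a doublet
NH2_H_WINDOW = (6.4, 7.8)  # ppm, 1H range of Asn/Gln NH2 resonances


@dataclass(frozen=True)
class Peak:
    """A single 2D cross peak.

    Parameters
    ----------
    id : str
        Opaque unique label within a list.
    h_ppm, n_ppm : float
        ¹H and ¹⁵N chemical shifts in ppm; must be finite.
    intensity : float, optional
        Peak height in arbitrary units.
    kind : str
        One of ``backbone_amide``, ``sidechain_nh2``, ``unknown``.
    assignment : str, optional
        Residue label if the peak is assigned.
    """

    id: str
    h_ppm: float
    n_ppm: float
    intensity: Optional[float] = None
    kind: str = UNKNOWN
    assignment: Optional[str] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h_ppm) and math.isfinite(self.n_ppm)):
            raise ValueError(f"peak {self.id!r}: non-finite chemical shift")
        if self.kind not in _KINDS:
            raise ValueError(f"peak {self.id!r}: unknown kind {self.kind!r}")


@dataclass
class PeakList:
    """An ordered collection of peaks with spectrum metadata.

    ``meta`` carries the spectrum label, acquisition temperature in K
    (default 303, the study-standard value for PAH1 work), field strength
    in MHz and free-text provenance.  Peak ids must be unique; order is
    preserved through read/write round trips.
    """

    peaks: list[Peak] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.meta.setdefault("label", "")
        self.meta.setdefault("temperature_K", 303.0)
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peak ids: {dup}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, peak_id: str) -> Peak:
        for p in self.peaks:
            if p.id == peak_id:
                return p
        raise KeyError(peak_id)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def drop(self, ids: Iterable[str]) -> "PeakList":
        """Return a copy without the named peaks (manual curation)."""
        drop = set(ids)
        missing = drop - set(self.ids)
        if missing:
            raise KeyError(f"unknown peak ids: {sorted(missing)}")
        return PeakList([p for p in self.peaks if p.id not in drop], dict(self.meta))

    def with_meta(self, **kwargs) -> "PeakList":
        meta = dict(self.meta)
        meta.update(kwargs)
        return PeakList(list(self.peaks), meta)


def _parse_float(token: str, path, lineno: int, what: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"{path}, line {lineno}: non-numeric {what} {token!r}") from None
    if not math.isfinite(value):
        raise ValueError(f"{path}, line {lineno}: non-finite {what} {token!r}")
    return value


def _read_sparky(path: Path, axis_order: str) -> PeakList:
    peaks: list[Peak] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # first non-comment line is the header
                continue
            tokens = line.split()
            if len(tokens) not in (3, 4):
                raise ValueError(
                    f"{path}, line {lineno}: expected 'Assignment w1 w2 [height]', got {len(tokens)} fields"
                )
            label = tokens[0]
            w1 = _parse_float(tokens[1], path, lineno, "w1 shift")
            w2 = _parse_float(tokens[2], path, lineno, "w2 shift")
            height = _parse_float(tokens[3], path, lineno, "height") if len(tokens) == 4 else None
            if axis_order == "n_h":
                n_ppm, h_ppm = w1, w2
            else:
                h_ppm, n_ppm = w1, w2
            peaks.append(
                Peak(
                    id=label,
                    h_ppm=h_ppm,
                    n_ppm=n_ppm,
                    intensity=height,
                    assignment=None if label == "?-?" else label,
                )
            )
    return PeakList(peaks, {"label": path.stem, "provenance": f"read from {path.name} (sparky)"})


def _read_csv(path: Path) -> PeakList:
    import csv as _csv

    peaks: list[Peak] = []
    with open(path, newline="") as fh:
        # skip provenance comment lines before the header
        rows = [
            (lineno, row)
            for lineno, row in enumerate(_csv.reader(fh), start=1)
            if row and not row[0].lstrip().startswith("#")
        ]
    if not rows:
        raise ValueError(f"{path}: no header row")
    _, header = rows[0]
    cols = [c.strip() for c in header]
    for required in ("id", "h_ppm", "n_ppm"):
        if required not in cols:
            raise ValueError(f"{path}: missing column {required!r}")
    idx = {c: cols.index(c) for c in cols}
    for lineno, row in rows[1:]:
        if all(not c.strip() for c in row):
            continue
        get = lambda c: row[idx[c]].strip() if c in idx and idx[c] < len(row) else ""
        h = _parse_float(get("h_ppm"), path, lineno, "h_ppm")
        n = _parse_float(get("n_ppm"), path, lineno, "n_ppm")
        intensity = get("intensity")
        kind = get("kind") or UNKNOWN
        assignment = get("assignment") or None
        peaks.append(
            Peak(
                id=get("id"),
                h_ppm=h,
                n_ppm=n,
                intensity=float(intensity) if intensity else None,
                kind=kind,
                assignment=assignment,
            )
        )
    return PeakList(peaks, {"label": path.stem, "provenance": f"read from {path.name} (csv)"})


def read_peaklist(path, format: str = "sparky", sparky_axis_order: str = "n_h") -> PeakList:
    """Read a peak list from ``path`` in the named dialect.

    Parameters
    ----------
    format : {"sparky", "csv"}
    sparky_axis_order : {"n_h", "h_n"}
        Mapping of the Sparky w1/w2 columns onto nuclei; default reads
        w1 as ¹⁵N and w2 as ¹H.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "sparky":
        if sparky_axis_order not in ("n_h", "h_n"):
            raise ValueError(f"bad sparky_axis_order {sparky_axis_order!r}")
        return _read_sparky(path, sparky_axis_order)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown peak-list format {format!r}")


def write_peaklist(pl: PeakList, path, format: str = "sparky", sparky_axis_order: str = "n_h"):
    """Write ``pl`` to ``path``; shifts round-trip to 1e-4 ppm."""
    path = Path(path)
    prov = f"# sidmap peak list | label={pl.meta.get('label', '')}\n"
    if format == "sparky":
        with open(path, "w") as fh:
            fh.write(prov)
            fh.write(f"{'Assignment':>17s} {'w1':>10s} {'w2':>10s} {'Data Height':>14s}\n")
            for p in pl:
                w1, w2 = (p.n_ppm, p.h_ppm) if sparky_axis_order == "n_h" else (p.h_ppm, p.n_ppm)
                height = "" if p.intensity is None else f"{p.intensity:.6g}"
                fh.write(f"{p.id:>17s} {w1:>10.4f} {w2:>10.4f} {height:>14s}\n")
    elif format == "csv":
        with open(path, "w") as fh:
            fh.write(prov)
            fh.write("id,h_ppm,n_ppm,intensity,kind,assignment\n")
            for p in pl:
                height = "" if p.intensity is None else f"{p.intensity:.6g}"
                fh.write(
                    f"{p.id},{p.h_ppm:.4f},{p.n_ppm:.4f},{height},{p.kind},{p.assignment or ''}\n"
                )
    else:
        raise ValueError(f"unknown peak-list format {format!r}")
    return path


@dataclass
class ExclusionReport:
    """Which peaks :func:`exclude_sidechain_nh2` removed, and why."""

    removed_flagged: list[str] = field(default_factory=list)
    removed_heuristic: list[str] = field(default_factory=list)

    @property
    def removed(self) -> list[str]:
        return self.removed_flagged + self.removed_heuristic


def exclude_sidechain_nh2(pl: PeakList, heuristic: bool = False) -> tuple[PeakList, ExclusionReport]:
    """Remove Asn/Gln NH₂ side-chain peaks before shift comparison.

    Peaks annotated ``sidechain_nh2`` are always removed.  With
    ``heuristic=True``, unannotated peaks are additionally removed when
    they occur as a doublet: two peaks sharing ¹⁵N within
    ``NH2_N_TOLERANCE`` whose ¹H shifts both lie inside ``NH2_H_WINDOW``.
    Backbone-annotated peaks are never touched.  Idempotent.
    """
    report = ExclusionReport()
    kept: list[Peak] = []
    candidates: list[Peak] = []
    for p in pl:
        if p.kind == SIDECHAIN_NH2:
            report.removed_flagged.append(p.id)
        else:
            kept.append(p)
            lo, hi = NH2_H_WINDOW
            if heuristic and p.kind == UNKNOWN and lo <= p.h_ppm <= hi:
                candidates.append(p)

    if heuristic and len(candidates) >= 2:
        # pair nearest 15N neighbours among candidates, closest pairs first
        cand = sorted(candidates, key=lambda p: (p.n_ppm, p.id))
        pairs = []
        for a, b in zip(cand, cand[1:]):
            gap = abs(a.n_ppm - b.n_ppm)
            if gap <= NH2_N_TOLERANCE:
                pairs.append((gap, a.id, b.id))
        used: set[str] = set()
        for _, ida, idb in sorted(pairs):
            if ida in used or idb in used:
                continue
            used.update((ida, idb))
        report.removed_heuristic = sorted(used)
        kept = [p for p in kept if p.id not in used]

    return PeakList(kept, dict(pl.meta)), report
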