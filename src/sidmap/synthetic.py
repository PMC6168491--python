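"""Synthetic ¹⁵N-HSQC data with the statistical structure CSP analysis assumes.

No spectra were deposited for the PAH1:Tet1 system, so the toolkit is
exercised on generated data: an apo peak list drawn uniformly over the
amide region, complex lists in which a fixed interface subset of peaks
is displaced (slow-exchange binding at 1:1 stoichiometry — peaks jump,
they do not walk), a mutant series in which each mutant scales the same
displacement field by an effect multiplier, and rendered 2D grids for
the peak-picking step.  Ground truth (interface membership, true
per-peak shifts) is returned alongside so recovery can be scored.

The ``fig4b`` scenario mirrors a wild-type + five point mutants series:
multipliers are calibrated so the apo-vs-WT average minimal shift lands
near 0.127 ppm and the mutant-vs-WT ordering follows the residue
importance ranking L897 > L900 > I894 > T898.  Those anchors shape the
simulation; they are not recomputed measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import WeightingScheme
from .peaklist import BACKBONE_AMIDE, SIDECHAIN_NH2, Peak, PeakList

__all__ = [
    "PerturbationScenario",
    "SeriesResult",
    "make_apo_peaklist",
    "make_complex_series",
    "render_grid",
    "fig4b_scenario",
    "FIG4B_MULTIPLIERS",
    "plant_sid_scenario",
]

H_RANGE = (6.5, 10.5)  # ppm, amide 1H region
N_RANGE = (103.0, 133.0)  # ppm, amide 15N region

# Effect multipliers for the wild-type + mutant series: fraction of the
# full WT displacement field each complex realises. Derived once from the
# anchor delta_min ratios (mutant-vs-WT / apo-vs-WT) of the target series.
FIG4B_MULTIPLIERS = {
    "WT": 1.0,
    "L897A": 0.07,
    "L900A": 0.42,
    "I894A": 0.52,
    "T898E": 0.70,
    "T898A": 0.80,
}

# Mean weighted displacement (ppm) of an interface peak in the WT complex;
# calibrated by simulation so delta_min(apo, WT) sits near the 0.127 ppm
# anchor under the default scenario.
FIG4B_MEAN_SHIFT = 0.47


@dataclass
class PerturbationScenario:
    """Parameters of a synthetic binding-perturbation experiment.

    interface_fraction
        Fraction of apo peaks that move on complex formation (the size
        of the binding interface is not known; 0.3 is a guess).
    mean_shift
        Mean weighted displacement magnitude (ppm) of an interface peak
        at multiplier 1; magnitudes are Gamma(shape=2) distributed.
    effect_multipliers
        label → scaling of the shared displacement field.
    jitter_sigma
        Isotropic measurement noise (ppm, weighted space) added to every
        peak of every list, including a re-measured apo.
    substoichiometric
        If > 0, fraction of interface peaks that additionally retain an
        apo-position twin (the doubled peaks of partial saturation in
        slow exchange). Off by default.
    """

    interface_fraction: float = 0.3
    mean_shift: float = 0.1
    effect_multipliers: dict[str, float] = field(default_factory=lambda: {"WT": 1.0})
    jitter_sigma: float = 0.004
    substoichiometric: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.interface_fraction <= 1.0:
            raise ValueError("interface_fraction must be in [0, 1]")
        if not 0.0 <= self.substoichiometric <= 1.0:
            raise ValueError("substoichiometric must be in [0, 1]")
        if any(m < 0 for m in self.effect_multipliers.values()):
            raise ValueError("effect multipliers must be >= 0")
        if self.mean_shift < 0 or self.jitter_sigma < 0:
            raise ValueError("mean_shift and jitter_sigma must be >= 0")


@dataclass
class SeriesResult:
    """Synthetic complex series plus ground truth."""

    lists: dict[str, PeakList]  # includes a re-jittered "apo"
    interface_ids: list[str]
    true_shifts: dict[str, dict[str, float]]  # label -> peak id -> weighted ppm


def make_apo_peaklist(
    n: int = 90,
    seed: int = 0,
    n_nh2_pairs: int = 0,
    min_separation: float = 0.05,
    scheme: WeightingScheme = WeightingScheme(),
) -> PeakList:
    """Uniform random apo amide peak list with a crowding floor.

    Peaks fall in ¹H 6.5–10.5 × ¹⁵N 103–133 ppm with pairwise weighted
    separation ≥ ``min_separation`` (rejection sampling).  Optionally
    appends flagged Asn/Gln NH₂ doublets.  Deterministic per seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    accepted: list[tuple[float, float]] = []  # weighted coords (h, n/w)
    attempts = 0
    max_attempts = 2000 * max(n, 1)
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} peaks at separation {min_separation} ppm "
                f"within {max_attempts} attempts"
            )
        h = rng.uniform(*H_RANGE)
        npp = rng.uniform(*N_RANGE)
        cand = (h, npp / scheme.n_weight)
        if all(np.hypot(cand[0] - x, cand[1] - y) >= min_separation for x, y in accepted):
            accepted.append(cand)

    peaks = [
        Peak(
            id=f"a{i + 1:03d}",
            h_ppm=round(h, 4),
            n_ppm=round(y * scheme.n_weight, 4),
            intensity=float(rng.uniform(0.5, 1.5)),
            kind=BACKBONE_AMIDE,
        )
        for i, (h, y) in enumerate(accepted)
    ]
    for j in range(n_nh2_pairs):
        # NH2 doublet: shared 15N, two 1H positions in the side-chain window
        npp = float(rng.uniform(109.0, 113.0))
        h1 = float(rng.uniform(6.6, 7.1))
        h2 = h1 + float(rng.uniform(0.4, 0.7))
        for tag, h in (("a", h1), ("b", h2)):
            peaks.append(
                Peak(
                    id=f"nh2_{j + 1}{tag}",
                    h_ppm=round(h, 4),
                    n_ppm=round(npp + rng.uniform(-0.05, 0.05), 4),
                    intensity=float(rng.uniform(0.3, 0.8)),
                    kind=SIDECHAIN_NH2,
                )
            )
    return PeakList(peaks, {"label": "apo", "provenance": f"make_apo_peaklist(n={n}, seed={seed})"})


def _jittered(pl: PeakList, rng: np.random.Generator, sigma: float, scheme: WeightingScheme, label: str) -> PeakList:
    peaks = []
    for p in pl:
        dh = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        dn = rng.normal(0.0, sigma) * scheme.n_weight if sigma > 0 else 0.0
        peaks.append(
            Peak(
                id=p.id, h_ppm=p.h_ppm + dh, n_ppm=p.n_ppm + dn,
                intensity=p.intensity, kind=p.kind, assignment=p.assignment,
            )
        )
    return PeakList(peaks, {"label": label, "provenance": f"synthetic series label={label}"})


def make_complex_series(
    apo: PeakList,
    scenario: PerturbationScenario,
    scheme: WeightingScheme = WeightingScheme(),
) -> SeriesResult:
    """Generate labelled complex peak lists from an apo list.

    One interface subset and one displacement field (direction + base
    magnitude per interface peak) are drawn per scenario and shared by
    every label, scaled by that label's effect multiplier — a mutant
    complex moves the same peaks in the same directions, just less far.
    Isotropic measurement jitter is then added independently to every
    list, including a regenerated ``apo``.
    """
    if len(apo) == 0:
        raise ValueError("apo list is empty")
    rng = np.random.default_rng(scenario.seed)
    backbone = [p for p in apo if p.kind != SIDECHAIN_NH2]
    n_interface = int(round(scenario.interface_fraction * len(backbone)))
    interface_ids = sorted(
        rng.choice([p.id for p in backbone], size=n_interface, replace=False).tolist()
    )

    # shared displacement field in weighted shift space
    direction = rng.uniform(0.0, 2.0 * np.pi, size=n_interface)
    magnitude = rng.gamma(shape=2.0, scale=scenario.mean_shift / 2.0, size=n_interface)
    disp = {
        pid: (m * np.cos(a), m * np.sin(a), m)
        for pid, a, m in zip(interface_ids, direction, magnitude)
    }

    lists: dict[str, PeakList] = {}
    true_shifts: dict[str, dict[str, float]] = {}
    lists["apo"] = _jittered(apo, rng, scenario.jitter_sigma, scheme, "apo")
    true_shifts["apo"] = {p.id: 0.0 for p in apo}

    for label, mult in scenario.effect_multipliers.items():
        if label == "apo":
            raise ValueError("label 'apo' is reserved for the regenerated reference")
        peaks = []
        shifts: dict[str, float] = {}
        for p in apo:
            if p.id in disp:
                dx, dy, m = disp[p.id]
                h = p.h_ppm + mult * dx
                npp = p.n_ppm + mult * dy * scheme.n_weight
                shifts[p.id] = mult * m
                if scenario.substoichiometric > 0 and rng.random() < scenario.substoichiometric:
                    # partial saturation: the apo-position twin survives
                    peaks.append(
                        Peak(id=f"{p.id}_apo", h_ppm=p.h_ppm, n_ppm=p.n_ppm,
                             intensity=p.intensity, kind=p.kind)
                    )
            else:
                h, npp = p.h_ppm, p.n_ppm
                shifts[p.id] = 0.0
            peaks.append(Peak(id=p.id, h_ppm=h, n_ppm=npp, intensity=p.intensity, kind=p.kind))
        complex_pl = PeakList(peaks, {"label": label})
        lists[label] = _jittered(complex_pl, rng, scenario.jitter_sigma, scheme, label)
        true_shifts[label] = shifts

    return SeriesResult(lists=lists, interface_ids=interface_ids, true_shifts=true_shifts)


def fig4b_scenario(seed: int = 0, n_peaks: int = 72) -> tuple[PeakList, PerturbationScenario]:
    """Apo list + scenario emulating a wild-type/mutant HSQC series.

    72 backbone peaks (matched counts then land in the typical 70–75
    range for a PAH1-sized domain), interface fraction 0.3, and the
    calibrated multiplier set ordered WT > T898A > T898E > I894A >
    L900A > L897A.
    """
    apo = make_apo_peaklist(n=n_peaks, seed=seed)
    scenario = PerturbationScenario(
        interface_fraction=0.3,
        mean_shift=FIG4B_MEAN_SHIFT,
        effect_multipliers=dict(FIG4B_MULTIPLIERS),
        jitter_sigma=0.004,
        seed=seed + 1,
    )
    return apo, scenario


def render_grid(
    pl: PeakList,
    linewidth_h: float = 0.02,
    linewidth_n: float = 0.25,
    grid_shape: tuple[int, int] = (256, 512),
    noise_sigma: float = 0.0,
    seed: int = 0,
    default_intensity: float = 1.0,
):
    """Render a peak list as a 2D Gaussian-sum grid plus white noise.

    Linewidths are Gaussian sigmas in ppm; the axes cover the peak
    bounding box padded by 5 linewidths.  ``grid_shape`` is
    (n-axis points, h-axis points).
    """
    from .picking import SpectrumGrid

    if len(pl) == 0:
        raise ValueError("cannot render an empty peak list")
    if linewidth_h <= 0 or linewidth_n <= 0:
        raise ValueError("linewidths must be > 0")
    rng = np.random.default_rng(seed)
    h = np.array([p.h_ppm for p in pl])
    n = np.array([p.n_ppm for p in pl])
    amp = np.array([p.intensity if p.intensity is not None else default_intensity for p in pl])

    h_axis = np.linspace(h.min() - 5 * linewidth_h, h.max() + 5 * linewidth_h, grid_shape[1])
    n_axis = np.linspace(n.min() - 5 * linewidth_n, n.max() + 5 * linewidth_n, grid_shape[0])
    H, N = np.meshgrid(h_axis, n_axis)
    data = np.zeros(grid_shape, dtype=float)
    for hi, ni, ai in zip(h, n, amp):
        data += ai * np.exp(
            -0.5 * (((H - hi) / linewidth_h) ** 2 + ((N - ni) / linewidth_n) ** 2)
        )
    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma, size=grid_shape)
    return SpectrumGrid(intensities=data, h_axis=h_axis, n_axis=n_axis)


# ---------------------------------------------------------------------------
# planted-SID sequence scenario for the scanning module

_POLAR = "DEKRNQSTHP"  # background alphabet: no motif-capable hydrophobics
_PLANT = "AIEALTKLQES"  # amphipathic 11-mer with the short/long pair motif


def plant_sid_scenario(
    seed: int = 0,
    length: int = 200,
    n_species: int = 6,
    background_mutation_rate: float = 0.5,
) -> tuple[str, list[str], int]:
    """A random polar sequence with one conserved amphipathic SID planted.

    Returns ``(sequence, msa_rows, plant_start_0based)``.  The alignment
    has ``n_species`` rows; the planted window is perfectly conserved
    while background columns mutate independently at the given rate, so
    both the moment and the conservation signal point at the plant.
    """
    rng = np.random.default_rng(seed)
    bg = rng.choice(list(_POLAR), size=length)
    start = int(rng.integers(0, length - len(_PLANT) + 1))
    seq = bg.copy()
    seq[start : start + len(_PLANT)] = list(_PLANT)
    query = "".join(seq)

    rows = [query]
    for _ in range(n_species - 1):
        row = list(query)
        for j in range(length):
            inside = start <= j < start + len(_PLANT)
            if not inside and rng.random() < background_mutation_rate:
                row[j] = rng.choice(list(_POLAR))
        rows.append("".join(row))
    return query, rows, start
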