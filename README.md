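# sidmap

Discovery and NMR-based characterisation of **Sin3-interaction domains
(SIDs)** — the short amphipathic helices with which transcriptional
repressors (and the 5mC dioxygenase Tet1) dock into the hydrophobic
cleft of a Sin3A paired-amphipathic-helix (PAH) domain.

The package covers the three computational legs of that kind of study:

1. **Sequence side** — nominate candidate SIDs by sliding-window
   scoring: helical-wheel geometry (100°/residue), the Eisenberg
   hydrophobic moment μH, hydrophobic-face detection (minimal covering
   arc on the wheel), the lock-and-key motif of a short hydrophobic
   pair at offsets *i*, *i*+3 followed by a long pair at *i*+4, *i*+7
   (the Tet1 A893/A896 + L897/L900 arrangement), and column
   conservation of a multiple alignment.
2. **Spectrum side** — minimal chemical-shift mapping between
   ¹⁵N-HSQC peak lists when assignments are unavailable: automatic
   peak picking at a multiple (default 1.4) of the robust noise level,
   exclusion of Asn/Gln NH₂ side-chain peaks, one-to-one
   minimal-distance matching (exact assignment-problem optimum, with a
   greedy alternative), weighted distances
   Δδ = √(Δδ_H² + (Δδ_N/7)²), and the per-comparison average minimal
   shift **Δδ_min = Σ matched Δδ / n_matched**.  Because the matching
   minimises total distance, Δδ_min is a lower bound on the true
   average perturbation.
3. **Structure side** — helix-bundle superposition: read PDB models
   and HELIX records, pair backbone atoms (N, CA, C) over
   corresponding helices, Kabsch superposition, RMSD.

A first-class synthetic-data module emulates slow-exchange binding
series (apo + wild-type + mutant complexes that scale a shared
displacement field), so the entire analysis chain runs and is tested
without any deposited spectra.

## Worked example

Generate a synthetic mutant series and quantify each residue's
contribution to binding, exactly as one would with measured peak lists:

```python
from sidmap import (fig4b_scenario, make_complex_series,
                    minimal_shift_summary, compare_series)

apo, scenario = fig4b_scenario(seed=6)      # 72 amide peaks, 6 complexes
series = make_complex_series(apo, scenario)

s = minimal_shift_summary(series.lists["apo"], series.lists["WT"])
print(f"apo vs WT: delta_min = {s.delta_min:.3f} ppm over {s.n_matched} matched peaks")

table = compare_series(series.lists["WT"],
                       {m: series.lists[m] for m in
                        ["L897A", "L900A", "I894A", "T898E", "T898A"]})
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints

```
apo vs WT: delta_min = 0.125 ppm over 72 matched peaks
label  delta_min  n_matched  rank    mode
L897A      0.117         72     1 optimal
L900A      0.075         72     2 optimal
I894A      0.065         72     3 optimal
T898E      0.044         72     4 optimal
T898A      0.031         72     5 optimal
```

The apo-vs-WT row sizes the full binding perturbation (~0.13 ppm
averaged over all matched amides).  Each mutant row is computed against
the **wild-type complex**, so a large Δδ_min means the mutated residue
mattered: the ranking L897A > L900A > I894A > T898E > T898A recovers
the effect-multiplier ordering planted by the generator — the L897A
complex looks most like the apo protein (binding lost), while T898A is
nearly indistinguishable from wild type.

The same sequence-side call on the bundled Tet1-SID window fixture:

```python
from sidmap.sid import TET1_SID_FIXTURE, hydrophobic_face, sid_motif_match
face = hydrophobic_face(TET1_SID_FIXTURE)   # residues (893, 894, 896, 897, 900), arc 160.0
sid_motif_match(TET1_SID_FIXTURE)           # (True, 0): short/long pair motif at 893
```

places the five hydrophobic residues on a single helical face (minimal
arc 160° ≤ 180°) with the SID motif anchored at residue 893.

There is also a CLI: `sidmap simulate`, `sidmap pick`, `sidmap
minshift`, `sidmap compare`, `sidmap scan-sid`, `sidmap rmsd` — run any
of them with `--help`.  `sidmap rmsd --ref 2rms.pdb --mov 2czy.pdb`
reproduces the classic PAH1 four-helix comparison if you download those
two entries.

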