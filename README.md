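# pvdarbor

Morphometrics of *C. elegans* PVD dendrite arbors on the cylindrical body
surface.

The PVD nociceptive neuron tiles the worm's skin with a stereotyped lattice
of "menorahs": a primary (1°) dendrite runs anteriorly and posteriorly from
the soma along the lateral line, secondary (2°) stems extend dorsally and
ventrally to the sublateral lines, tertiary (3°) bases grow along those
lines, and quaternary (4°) candles reach toward the dorsal and ventral
nerve cords. Sibling 3° dendrites that touch normally retract
(*self-avoidance*), leaving visible gaps between neighbouring menorahs.
Mutants break this pattern in characteristic ways — failed 2° branching,
2° dendrites trapped along the 1° axis, or persistent 3° contacts and
overlaps.

`pvdarbor` is for researchers quantifying such phenotypes from traced
skeletons. It provides:

- **Branch-order classification** of unlabeled SWC skeletons using the
  orientation-alternation rule of the PVD lattice (axial 1° → circumferential
  2° → axial 3° → circumferential 4°), including axon/AIS and trapped-2°
  detection.
- **Self-avoidance statistics** — the tertiary branch avoidance index
  TBAI = G/M (visible gaps between neighbouring 3° branches over menorah
  count), overlapped-3° counts, and mean inter-3° gaps in configurable
  anterior scoring windows.
- **Coverage metrics** — the receptive-field index
  RFI = innervated skin area / body skin area from soma to mouth, and the
  menorah-coverage and trapped-2° zones along the 1° dendrite.
- **Surface unrolling** — the isometry (s, θ) ↦ (u, v) = (s, r·Δθ) and
  consolidated 4°-termini scatter maps scaled to each worm's circumference,
  with the dorsal/ventral cord lines exactly half a circumference apart.
- **Fluorescence quantification** — photoconversion recovery fractions
  (Fₙ−F₀)/(Fₚ−F₀), saturating-exponential rate fits, repeated-measures
  two-way ANOVA cohort comparison, and a permutation test for mRNA-puncta
  enrichment at branch points and retracted contact points.
- **A synthetic arbor generator** that emulates wildtype-like and
  mutant-like phenotypes with full per-edge ground truth, so every stage is
  testable without microscopy data.

All distances are geodesics on the cylinder, `ds² = dS² + (r·dθ)²`, in
micrometres. Skeletons travel as plain SWC plus a small JSON sidecar
carrying the body geometry (length, radius, soma and mouth positions,
dorsal-midline angle).

## Worked example

```python
import pvdarbor as pa

for name in ("wildtype_like", "xr58_like"):
    graph, truth = pa.generate_arbor(pa.preset(name, seed=1))
    labeled = pa.assign_orders(graph)
    tb, M, G = pa.tbai(labeled)
    rep = pa.compute_report(labeled)
    print(f"{name}: TBAI = {tb:.3f} ({G} gaps / {M} menorahs), "
          f"RFI = {rep.rfi:.3f}, trapped zone = {rep.trapped_zone_um:.1f} um")
```

prints

```
wildtype_like: TBAI = 0.862 (25 gaps / 29 menorahs), RFI = 0.354, trapped zone = 0.0 um
xr58_like: TBAI = 0.138 (4 gaps / 29 menorahs), RFI = 0.362, trapped zone = 0.0 um
```

Both arbors carry 29 menorahs — the self-avoidance-defective preset
branches normally — but almost every neighbouring 3° pair that would leave
a visible gap in the healthy arbor instead stays in contact, collapsing
TBAI from 0.86 to 0.14.

The same pipeline runs from the shell:

```sh
pvd simulate --preset wildtype_like --n 10 --seed 7 --out out/wt
pvd classify out/wt/*.swc --out out/wt_labeled
pvd measure out/wt_labeled/*.labeled.swc --out out/wt.csv --genotype wt
pvd report out/wt.csv out/mut.csv --out out/tests --metric tbai --design ttest
```

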