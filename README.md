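# chipcyto

A desk-scale simulator and analysis package for **on-chip imaging flow
cytometry with electrophoretic sorting**. It models a PMMA microfluidic
cell-sorter chip in which a sample stream is narrowed by sheath buffer flows
(hydrodynamic focusing, 50 μm → 5 μm at a 1:10 width ratio), particles pass
single-file through a 50 μm × 25 μm × 100 μm sorting segment imaged by a
high-speed camera at 200 frames/s, a real-time recognizer classifies each
particle from its bright-field image, and a DC field across agarose gel
electrodes deflects selected particles into a two- or three-way outlet.

The package is for anyone who wants to study, reproduce, or extend the
*computational* behaviour of such an instrument without hardware: it generates
ground-truthed synthetic frame stacks, runs the recognition/gating pipeline on
them (or on user-supplied stacks in the same format), simulates the sorting
physics, and evaluates the instrument's performance envelope.

## The models at its core

**Recognition** (per frame): subtract the stored background image `B` from the
frame `F`, binarize `|F − B| ≥ θ` at a preset threshold, extract connected
components, and compute per-blob features — mean intensity, area `A`,
equivalent-ellipse major/minor axes from second central moments, and
circularity `4πA/P²` with a bias-corrected boundary-chain perimeter `P`.
Gating applies interval predicates over these features (first matching rule
wins); two populations of similar size are separated by a blob-area threshold
fitted to minimize misclassification on a calibration split.

**Sorting**: a particle of electrophoretic mobility μ crossing the sorting
segment of length `L` at speed `v` under voltage `V` across gap `g` drifts
laterally by `Δx = μ·(V/g)·(L_eff/v)`, with `L_eff` reduced by the decision
latency. It changes outlet when `x + Δx` reaches the branch line (3 μm from
the centerline for the default chip).

**Throughput**: the sorting segment images a sensing volume
`W·H·L = 125 pL` per event. At the 200 events/s recognition cap and 1:10
sheath ratio the maximum sample-processing rate is `125 pL × 200/s ÷ 10 =
2.5 nL/s`; one particle per sensing volume caps the density at
`1/125 pL = 8 × 10⁶ /mL`; and with occupancy `λ = ρ·V_sense` the coincidence
("entanglement") probability is Poisson, `P(N≥2) = 1 − e^{−λ}(1+λ)`.

## Worked example

```sh
python examples/throughput_report.py
```

```
sensing volume:        125 pL
max processing rate:   2.50 nL/s
sorting-area speed:    20 mm/s
max density:           8.00e+06 /mL
occupancy lambda:      0.125 at 1e+06 /mL
coincidence P(N>=2):   0.72%
processing time (5uL): 33.3 min
total with setup:      38.3 min
```

Reading: the default chip at its recognition cap processes a 5 μL sample in
about 33 minutes (38 with automated setup), and at 10⁶ particles/mL fewer
than 0.8% of events contain two entangled particles.

```sh
python examples/size_benchmark.py
```

```
fitted area gate:      6.28 um^2
held-out error:        0.33% (n = 300, 0 undetected)
confusion (rows=truth small/large, cols=predicted):
[[157   1]
 [  0 142]]
2.5um: area histogram peak at 5.0-5.5 um^2
3.0um: area histogram peak at 7.5-8.0 um^2
```

Reading: 2.5 μm and 3.0 μm polystyrene project 4.9 vs 7.1 μm² discs, so an
area gate fitted on half the particles separates the held-out half with well
under 2% error; the rare residuals are Poisson coincidences merging two
particles into one blob.

Other examples: `examples/simulate_and_detect.py` (render frames, detect, and
compare with ground truth) and `examples/sorting_sweep.py` (efficiency versus
voltage and flow rate, three-way charge separation).

A thin CLI wraps the same functions:

```sh
chipcyto simulate --config run.yaml --out simdir/
chipcyto detect simdir/frames.tiff simdir/background.tiff --config run.yaml --out events.csv
chipcyto sort events.csv simdir/truth.csv --config run.yaml --out outcomes.csv
chipcyto benchmark-size --small 2.5 --large 3.0 --seed 1
chipcyto throughput
```

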