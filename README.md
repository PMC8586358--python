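# pharmstorm

Quantitative analysis of pharmacoprobe single-molecule localization
microscopy (SMLM/dSTORM) data: localization-point density quantification,
complete-spatial-randomness null models, structure-association and
convex-hull distance statistics, single-molecule blink stoichiometry, and
receptor binding-curve fits — together with a ground-truth scene simulator
that makes every stage verifiable.

## The problem

Fluorophore-tagged drugs ("pharmacoprobes") imaged by dSTORM mark
individual drug–target binding events as localization points (LPs) with
~10 nm precision, while an antibody channel and binarized confocal masks
supply the anatomical context (axon varicosities, membrane contours).  The
scientific questions are spatial and stoichiometric: how dense is the drug
signal per µm² of membrane or tissue, is it clustered or random, does it
enrich on or avoid labeled structures, is there nanoscale order around
nerve terminals, and what affinity does the probe show in saturation and
functional assays?  This package implements that analysis stack for
anyone working with SMLM molecule lists, and replaces the microscope with
a simulator for development and validation.

## The statistics at its core

* **Density**: LP count over a polygon ROI or the centered inner camera
  window (inner 64×64 px of a 256×256 px field at 160 nm/px = 104.86 µm²),
  background-corrected by subtracting the density of probe-free control
  fields; two-channel experiments are summarized by the pharmacoprobe /
  antibody LP ratio normalized to the vehicle-group mean.
* **Nearest-neighbor distances (NND)** vs a matched uniform randomization,
  compared by a two-sample Kolmogorov–Smirnov test.  Under CSR with
  intensity λ the NND CDF is `1 − exp(−λπr²)`.
* **Dilation-ratio structure association**: density of LPs on a binarized
  structure divided by the density over its neighborhood built by 50
  iterations of a 3×3 binary dilation at a 10 nm grid (≈500 nm reach);
  1 under randomness, >1 for enrichment, <1 for avoidance.  A two-tailed
  Wilcoxon signed-rank test across images tests the median against 1, and
  the identical measurement on randomized LPs is the control.
* **Convex-hull surface distances**: a 2D hull is fitted to each bouton's
  antibody LPs; every drug LP within 1000 nm contributes its minimum
  distance to a hull boundary (0 inside), compared to a randomized null.
* **Stoichiometry**: chained density-linkage blink clustering; the
  single-LP fraction separates one-fluorophore probes (~78 %) from
  multi-fluorophore antibodies (~36 %), and the cluster scatter (sample SD
  about the centroid, axes averaged) estimates lateral localization
  precision.
* **Binding curves**: one-site saturation `B = Bmax·c/(c+Kd)` and the
  log-logistic concentration–response
  `R = baseline + (Emax−baseline)/(1+10^((logEC50−log c)·h))`, fitted by
  multi-start least squares.

## Worked example

`examples/` contains one short script per capability.  For instance,
`python examples/04_structure_association.py` prints:

```
enriched  median ratio  3.59 (Wilcoxon vs 1: p=0.0005) | randomized control  0.98 (p=0.5186)
random    median ratio  0.99 (Wilcoxon vs 1: p=0.3394) | randomized control  0.94 (p=0.9097)
avoiding  median ratio  0.11 (Wilcoxon vs 1: p=0.0005) | randomized control  0.99 (p=0.6221)
```

Twelve synthetic images are generated per scenario; the dilation-ratio
statistic correctly reads enrichment (>1), randomness (≈1) and avoidance
(<1), while re-randomizing the same LPs always returns ≈1.  Similarly,
`python examples/07_binding_curves.py` fits a noisy saturation series and
a control/antagonist-pretreated curve pair:

```
one-site fit: Kd = 134.0 nM (SE 8.4), Bmax = 103.0 (true: Kd 123, Bmax 100)
half-maximal occupancy on the fitted curve at c = Kd: 0.500 of Bmax
sigmoid fits: EC50 1.047 nM (control) vs 256.1 nM (pretreated)
rightward shift: 244.6-fold — the signature of a competitive antagonist occupying the receptor
```

The same stages run from the shell (`pharmstorm simulate|density|nnd|
structure-ratio|hull-distance|stoichiometry|fit-binding|run|report`) or as
a config-driven pipeline (`examples/08_pipeline_run.py`), which writes a
checksummed manifest reproducible under a fixed seed.

## Layout

```
src/pharmstorm/   core containers, io, simulate, density, spatial,
                  stoichiometry, binding, pipeline, cli
examples/         one narrative script per capability
tests/            unit, property and end-to-end acceptance tests
docs/methods.md   models, parameters, numerical choices, limitations
```
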