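# sarcotrack

Quantification toolkit for studying how adult *Drosophila* muscles maintain
themselves. Adult indirect flight muscle is structurally static but keeps
transcribing and turning over its sarcomeric proteins; when that ongoing
synthesis is blocked, flies lose climbing ability and sarcomere length
drifts. `sarcotrack` implements the five quantitative analyses such a study
rests on, together with a synthetic-data generator that produces every
input with known ground truth, so the whole pipeline is testable without
any microscopy or assay data:

* **Sarcomere morphometry** — sub-pixel Z-disc/M-line detection on
  fluorescence intensity profiles; sarcomere length (SL) as peak spacing,
  thin-filament length (TFL) as the distance from the Z-disc to the point
  halfway down the intensity slope into the H-zone, and H-zone width (HZ)
  as the span between the two half-slope crossings, with the closure
  identity SL = 2·TFL + HZ.
* **Pulse-chase turnover** — Z-disc intensity time courses, the Z-disc /
  sarcomere-body enrichment ratio, onset of incorporation (sustained
  one-sided t-test over the t=0 baseline), peak time, and a
  single-exponential decay half-life, ln 2/|slope| of log(mean − baseline)
  after the peak.
* **Comparative-Ct qPCR** — relative expression 2^−ΔΔCt with an internal
  reference gene and genotype-matched day-0 calibrators; percent
  knockdown 100·(1 − fold).
* **Negative-geotaxis screen scoring** — per-vial success fractions,
  day-0-normalised trajectories, total percent decline, day of sustained
  complete loss, and severity classes (Severe ≤ 9 d, Intermediate 12–21 d,
  Weak ≥ 24 d, None) on a 3-day assay grid.
* **GO enrichment and networks** — per-class enrichment ratios
  (k_class/n_class)/(K/N) and a severity-coloured interaction multigraph
  with GraphML/TSV round-tripping.

## Worked example

`examples/` holds one short script per capability. For instance,
morphometry on two synthetic groups (`python examples/01_morphometry.py`):

```
control: SL = 3.361 ± 0.004 µm (n=40 sarcomeres), TFL = 1.578 µm, HZ = 0.205 µm
knockdown: SL = 3.097 ± 0.003 µm (n=40 sarcomeres), TFL = 1.446 µm, HZ = 0.205 µm
difference: -7.8% (t = 49.2, p = 1.9e-60, ***)
```

The generator's ground truth was 3.36 µm for the control group and 3.10 µm
for the knockdown-like group: the pipeline recovers both means to well
within one 0.05 µm pixel, attributes the shortening to thin-filament
length, and the equal-variance Student's t-test flags the difference at
the `***` level (p < 0.0005). Similarly, `examples/04_geotaxis_screen.py`
scores a simulated 30-day climbing assay (81.3% decline for a design with
a true 82% linear decline) and classifies a 132-gene screen fixture back
into its designed 5/13/28/86 severity counts.

A thin CLI wraps the same library code for batch runs:

```sh
sarcotrack simulate --seed 1 --out run1   # synthetic inputs + truth sidecars
sarcotrack morph --out run1               # per-sarcomere SL/TFL/HZ tables
sarcotrack run --config cfg.yaml          # YAML-configured multi-stage run
```

Every run writes a `manifest.json` with files, parameters and seeds; a
fixed seed reproduces all outputs byte for byte.

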