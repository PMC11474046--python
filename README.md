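# caulogrowth

Single-cell growth-rate dynamics for asymmetrically dividing bacteria.

Organisms such as *Caulobacter crescentus* divide asymmetrically into a
small, motile **swarmer** daughter and a larger, sessile **stalked**
daughter. The swarmer cell spends an extended G1 phase (no DNA replication)
before differentiating, and during that phase its growth rate transiently
drops — so the two progenies differ in average growth rate even in the same
medium. Quantifying this from timelapse microscopy requires a chain of
careful, convention-sensitive steps; `caulogrowth` implements that chain as
a reusable library and CLI for anyone analysing tracked single-cell data
from asymmetric dividers:

- **lineage tables** — mother/daughter/sister linkage from per-frame
  tracking records, with *two* birth definitions: visible daughter
  **separation**, or **cytokinesis** completion (mask split in the mother;
  quantities under this convention carry an asterisk, e.g. G1 duration\*);
- **growth rates** — whole-cycle average rate `λ = ln(A_d/A_b)/Δt`, smoothed
  instantaneous relative rate `r_i = (A_{i+1} − A_i)/(A_i·Δt_frame)`,
  exponential-fit residual scores, alignment onto cell-cycle units
  (0 = birth, 1 = division), bootstrap population curves, tempograms, and
  grouping by G1 duration;
- **foci** — diffraction-limited spot detection (difference-of-Gaussians +
  robust per-cell threshold + proximity merging) inside label masks, G1
  duration from the appearance of the second replication-marker focus, and
  unipolar/bipolar localisation calls;
- **curation** — the standard trajectory-quality filters (cycle length,
  area gain, instantaneous-rate bounds, complete lineage, progeny identity)
  with one reason code per violated rule;
- **statistics** — Mann–Whitney U (exact for small tie-free samples),
  two-sample Kolmogorov–Smirnov, Spearman rank correlation, percentile
  bootstrap CIs;
- **synthetic data** — a ground-truthed generator of lineages, tracked-area
  tables, focus schedules and rendered fluorescence/mask frames, with a
  parameterised G1-coupled growth-rate dip, asymmetric division, and a
  cytokinesis-to-separation delay, so every stage above is testable by
  parameter recovery.

## Worked example

```python
import numpy as np
import caulogrowth as cg
from caulogrowth.lineage import link_generations
from caulogrowth.pipeline import analyze_tracks

params = cg.SimParams(seed=1)                      # nutrient-replete defaults
truth, table = cg.simulate_lineage(params, n_generations=3, n_founders=8)

result = analyze_tracks(link_generations(table.to_dict("records")))
rates = {t: [result.profiles[c].avg_rate for c in result.retained
             if result.tracks[c].progeny_type == t]
         for t in ("swarmer", "stalked")}
sw, st = np.mean(rates["swarmer"]), np.mean(rates["stalked"])
print(f"mean growth rate: swarmer {sw:.5f}, stalked {st:.5f} min^-1")
print(f"Mann-Whitney p = {cg.mann_whitney_u(rates['swarmer'], rates['stalked']).p_value:.2e}")
pop = result.by_type["swarmer"]
print(f"swarmer trough at {pop.bin_centers[np.nanargmin(pop.mean_rate)]:.2f} cc units")
```

prints

```
mean growth rate: swarmer 0.00519, stalked 0.00554 min^-1
Mann-Whitney p = 3.46e-02
swarmer trough at 0.22 cc units
```

The swarmer progenies grow ~6% slower on average than their stalked
siblings, and their population growth-rate curve dips around 0.2 cell-cycle
units — the end of the average G1 phase under these generative parameters
(the retained cells here are the 48 of 120 simulated tracks that have a
complete mother→daughter cycle and pass every quality filter).

The same pipeline is available from the shell:

```
caulogrowth simulate --out run/ --config config.yaml
caulogrowth analyze  --tracks run/tracks.csv --foci run/foci.csv --out analysis/
caulogrowth report   --analysis analysis/ --out figures/
```

Every output directory receives a `config_used.yaml` snapshot; identical
config + seed reproduce byte-identical outputs.

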