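# kinetomech

Single-molecule analysis of kinetochore–microtubule attachment.

Kinetochores couple chromosomes to spindle microtubules, and they grip
the microtubule differently depending on which way they are pulled
relative to the filament's plus/minus polarity. Measuring that behavior
in vitro takes four distinct single-molecule assays, each with its own
quantitative analysis:

- **CoSMoS colocalization** (`kinetomech.cosmos`): which surface-tethered
  centromeric DNAs recruited a GFP-tagged kinetochore subunit. Spots are
  detected per channel (difference-of-Gaussians bandpass, subpixel 2-D
  Gaussian refinement), channels are registered with a least-squares
  affine map from fiducial beads, and a DNA site counts as colocalized
  when a GFP spot lies within radius *r* (default 1.5 px). Fractions are
  aggregated per field of view, mean ± SEM. The same module scores
  polarity-marked capture assays (dim plus end / bright minus end).
- **Photobleach copy counting** (`kinetomech.bleachsteps`): discrete
  downward bleaching steps counted by recursive binary segmentation with
  Welch's *t*-test (Bonferroni-corrected per segment) plus a merge pass;
  step counts estimate the number of GFP-tagged copies per assembly.
- **Flip-flop nanometry** (`kinetomech.flipflop`): a kinetochore tethered
  to the coverslip reorients 180° about its anchor with each reversal of
  a gentle buffer flow. The tether point is the midpoint of tracked spot
  positions flanking each reversal, and the distance of a tagged subunit
  from that tether, |(x̄ − t̂)·û|, maps intra-kinetochore architecture at
  nanometer scale. Displacement distributions are fit with single
  Gaussians or two-component mixtures (EM, BIC model selection).
- **Trap mechanics** (`kinetomech.trapmech`): laser-trap records give
  direction-resolved sliding friction γ = F/v (OLS speed per
  constant-force epoch, γ binned at 1 ± 0.5 pN) and force-ramp rupture
  strengths (0.25 pN/s ramp, snap-back detection, censoring at the
  ~23 pN trap load limit).

Because the original recordings are not publicly archived, the package
ships a first-class synthetic-data generator (`kinetomech.simgen`) that
emulates every input — two-channel spot fields, bleach staircases,
flip-flop trajectories, sliding and rupture records — with full ground
truth, so every estimator is testable end to end.

## Worked example

```python
from kinetomech import simgen, flipflop

cfg = simgen.FlipFlopConfig(
    displacement_by_direction=(("toward_plus", 37.0), ("toward_minus", 37.0)),
    loc_noise_sd=10.0, n_cycles=58, seed=21,
)
traj, schedule, truth = simgen.make_flipflop_trajectory(cfg)
intervals = flipflop.segment_intervals(traj, schedule)
tether, disp = flipflop.infer_tether_and_displacements(intervals, schedule.flow_axis)
fit = flipflop.fit_displacement_model(disp.displacement_nm.to_numpy(), k=1, seed=0)
print(f"displacement {fit.means[0]:.1f} +/- {fit.sem_means[0]:.1f} nm "
      f"(n={len(disp)} intervals)")
```

prints

```
displacement 37.2 +/- 0.1 nm (n=116 intervals)
```

i.e. the pipeline recovers the generating 37 nm tether distance from 116
noisy (10 nm localization noise) measurement intervals, with the SEM
from a 200-resample bootstrap.

The full simulate→analyze pipeline is also scriptable:

```bash
kinetomech report --config run.yaml --out results/
kinetomech simulate --kind rupture --seed 3 --out scratch/rup
kinetomech rupture scratch/rup/record.csv
```

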