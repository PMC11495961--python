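# peristartle

Quantification of receiver **startle responses** during animal courtship from
2-D pose-estimation keypoint tracks.

During bowerbird courtship the receiver stands between the bower walls while
the male performs discrete display elements, some of them vigorous
("high-intensity": body ripples and mock attacks). This package measures how
strongly the receiver's head moves right after a display element compared with
just before it, and asks — with an individual-balanced bootstrap — whether that
peri-event movement exceeds what random moments of the same recordings produce.
It is written for behavioural ecologists and neuroethologists who have
per-frame keypoint coordinates (from DeepLabCut-style pose detectors) plus an
event log, and want a reproducible peri-event movement analysis rather than
manual coding.

## The statistic

For each bout, **relative displacement** normalises the frame-to-frame beak
movement by the bird's mean body height (vertical beak-to-inter-tarsal-joint
extent, averaged over the bout):

    RD[t] = ||beak[t] − beak[t−1]|| / mean body height

so RD = 0.15 is a head movement of 15% of body size. Around each display
element starting at frame *s*, with baseline length *b* (default 10) and post
length *w*, the occurrence frame belongs to both segments:

    baseline = RD[s−b+1 … s],  post = RD[s … s+w−1]
    Δ_mean = mean(post) − mean(baseline)      (Δ_max analogous with maxima)

The group statistic is the **unweighted mean of per-male mean Δ**, so males
with hundreds of elements cannot dominate. Its null distribution is built by
drawing, for each male, as many random eligible frames as he contributed
elements (uniformly with replacement, pooled over his bouts), evaluating Δ at
each frame as a pseudo-event, averaging within and then across males; 1000
replicates give the 2.5/97.5% limits and an add-one empirical p-value
(two-sided by default). Robustness checks sweep the post window over 4–50
frames and the baseline over {5, 10, 15, 20}, and re-run the test with each
male left out. A separate cluster permutation test (males as exchangeable
units) contrasts the probability that a high-intensity element is followed by
a bower exit between bower owners and subordinate males; a binomial GLMM
variant (random intercepts for male and date, via R's lme4) is available.

Tracks are first velocity-cleaned: keypoints jumping more than 0.5 body
heights in one frame are removed, jumps between 0.25 and 0.5 are flagged for
inspection.

## Worked example

The generator emulates the study structure (30 fps, bouts of a few hundred
frames, two status groups, display elements with startle pulses time-locked to
element onsets) so the whole pipeline runs without field data. Here only
owners elicit startles (0.2 body heights):

```python
from peristartle import SimulationConfig, StartleResponseModel, simulate_dataset

config = SimulationConfig(
    n_owners=4, n_subordinates=4, bouts_per_male=(3, 5),
    bout_length_frames=(300, 600),
    startle_magnitude={"owner": 0.2, "subordinate": 0.0},
    seed=7,
)
dataset = simulate_dataset(config)
model = StartleResponseModel(dataset, intensity_class="high")
results = model.fit(reps=1000, seed=7)
print(results.summary())
```

```
Peri-event startle response: individual-balanced bootstrap
  statistic: delta_mean  (baseline 10 / post 10 frames)
  intensity class: high;  B = 1000 replicates;  tail = two_sided
  owner        n= 4 males,   64 elements: observed delta = +0.0305, null 95% [-0.0063, +0.0067], p = 0.001998 (significant)
  subordinate  n= 4 males,   58 elements: observed delta = +0.0007, null 95% [-0.0012, +0.0012], p = 0.2517 (not significant)
```

The owner group's observed Δ (+0.0305: post-element head movement elevated by
~3% of body height per frame) lies far outside its null's 95% band, so the
injected effect is recovered; the subordinate group's Δ sits inside its band.
`results.window_sweep()` returns the post-size grid,
`results.leave_one_out("owner")` the per-omitted-male stability table (here:
all four rows stay significant with no sign change).

The same pipeline runs from the shell:

```sh
peristartle simulate --seed 7 --out data/
peristartle run --config run.yaml --out out/   # clean → RD → Δ → bootstrap → sweep → exits
```

Input formats (documented in `peristartle.io`): `tracks.csv` with
`bout_id,frame,keypoint,x,y` in image coordinates (y down, 0-based contiguous
frames), `annotations.csv` with bout metadata and display events,
`exits.csv` with bower-exit frames.

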