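# dgpop

Population-coding analysis of sparse, binarized calcium-event recordings.

Miniscope imaging of hippocampal dentate-gyrus granule cells yields very
sparse activity: ~70 neurons per animal sampled at 3 Hz, with calcium
transients around 0.02 Hz per neuron, while the animal explores an open
field or runs a forced-alternation T-maze. `dgpop` implements the analysis
chain used to ask how behavioral information is represented in such
populations, and whether different information types (position, speed,
motion direction, current and future left/right location) are carried by
the same neurons or distributed independently:

- **Tuning** — occupancy-normalized spatial event-rate maps (Gaussian
  smoothing, σ = 2 cm), speed-tuning curves over three speed classes, and
  direction-tuning curves over eight arcs.
- **Information** — per-neuron information content in bits per transient,
  I = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄), with circular-shift shuffle nulls
  (1000 shuffles, 95th-percentile thresholds) and a population-level
  permutation test with Cohen's d.
- **LR index** — per-neuron left/right selectivity
  (r_L − r_R)/(r_L + r_R) in the T-maze forced-arm window (current arm) and
  decision window (future choice), with trial-label permutation nulls.
- **Decoding** — ridge (default) or MLP decoding of position, speed and
  direction from sliding windows of population activity with contiguous
  temporal cross-validation; leave-one-trial-out binary decoding of L/R;
  chance levels from decoders retrained on shuffled data.
- **Deletion analysis** — neuron-dropping curves under named deletion
  orders (by information rank or random), pairwise Cohen's-d effect sizes
  at the nine 90..10% retention points, the order × order mean-|d|
  independence matrix, and the deletion-order two-way ANOVA with
  Tukey–Kramer post hoc tests.
- **Synthetic data** — a first-class generator (trajectories, tuning
  structures, Poisson event trains, T-maze sessions) emulating the
  recordings' statistical structure, so the whole pipeline runs and is
  tested end-to-end without external data.
- **I/O** — plain-CSV interchange formats, ΔF/F event detection
  (4-MAD threshold, 0.2-s minimum decay), and a `dgpop` command-line
  interface.

See `docs/methods.md` for the full model and estimator documentation.

## Worked example

```python
import dgpop

# a 15-min synthetic open-field session, 70 tuned neurons
traj = dgpop.simulate_of_trajectory(duration=900, seed=1)
spec = dgpop.make_tuning_spec(n_neurons=70, seed=2, baseline_rate=0.1,
                              gain_ranges={"place_gain_max": 20.0})
rec = dgpop.generate_events(traj, spec, seed=3)
kin = dgpop.compute_kinematics(traj)
state = dgpop.discretize_states(kin, traj)

# spatial information of one neuron, with its shuffle null
res = dgpop.info_with_null(rec.events[:, 0], state.position_flat, traj.dt,
                           n_shuffles=1000, seed=0)
print(f"neuron 0 spatial information: {res.info:.2f} bits/transient "
      f"(null 95th pct {res.null_p95:.2f}, significant: {res.exceeds_p95})")

# population-level permutation test
results = [dgpop.info_with_null(rec.events[:, i], state.position_flat,
                                traj.dt, n_shuffles=1000, seed=i)
           for i in range(rec.n_neurons)]
pop = dgpop.population_info_test(results, seed=0)
print(f"population: p = {pop.p_value:.3g}, Cohen's d = {pop.cohens_d:.2f}, "
      f"{pop.frac_above_p95:.0f}% of neurons above their null p95")

# position decoding vs shuffled-data chance
dec = dgpop.train_and_decode(rec, traj, target="position", window=10, seed=0)
chance = dgpop.chance_level(rec, traj, target="position", window=10,
                            n_reps=5, seed=0)
print(f"position decoding MAE: {dec.metric_value:.1f} cm "
      f"(shuffled-data chance {chance.mean():.1f} cm)")
```

Output:

```
neuron 0 spatial information: 1.08 bits/transient (null 95th pct 1.08, significant: False)
population: p = 0.000999, Cohen's d = 1.39, 67% of neurons above their null p95
position decoding MAE: 8.2 cm (shuffled-data chance 18.1 cm)
```

Neuron 0 happens to sit right at its own significance threshold, but the
population as a whole is strongly tuned (the permutation p-value is at its
1/1001 floor, i.e. "< 10⁻³"), and the population decoder localizes the
animal to within ~8 cm where decoders trained on shuffled data manage only
~18 cm — the chance level, close to always guessing the occupancy centroid.

The same pipeline runs from the shell:

```sh
dgpop simulate of --seed 1 --duration 900 --n-neurons 70 --out-dir session/
dgpop info --events session/events.csv --trajectory session/trajectory.csv \
      --variable position --out info.csv
dgpop decode of --events session/events.csv --trajectory session/trajectory.csv \
      --target position --out decoding.json
```

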