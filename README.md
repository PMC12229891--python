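# placeref

Reference-frame analysis of hippocampal CA1 place cells on circular
treadmill belts.

When a head-fixed mouse runs laps for a reward at a fixed belt
position, some CA1 place fields anchor to the belt's fixed tactile cues
(*space-referenced*) and others to the reward goal — more precisely, to
the running start that follows reward consumption (*goal-referenced*).
Moving the reward half a belt forward dissociates the two frames:
space-referenced fields stay put, goal-referenced fields rotate with
the reward. `placeref` implements the full analysis chain for this
paradigm, for experimentalists working with treadmill calcium imaging
and in vivo whole-cell recordings:

- **behavior**: lap segmentation, velocity/licking maps, detection of
  post-reward and non-rewarded running starts;
- **placecells**: dF/F extraction, significant transients, 50-bin
  spatial maps, onset lap, spatial information
  `SI = Σᵢ pᵢ·xᵢ·log₂|xᵢ/x̄|` with a circular-shift shuffle null, and
  reliability;
- **referencing**: classification by circular field shift (0–15 cm
  space, 75–90 cm goal, 16–74 cm intermediate), a random-remapping
  null (chance fraction 15/90 ≈ 0.167 per referenced category), and a
  cross-day bootstrap of the space/(space+goal) stability index;
- **population**: 50×50 population-vector Pearson matrices; diagonal
  mean = space similarity, 90-cm off-diagonal mean = goal similarity;
- **btsp**: detection of abrupt, persistent place-field formation
  (behavioral-timescale synaptic plasticity signatures: top-decile
  amplitude, >2 dF/F peak, persistence on 4 of 5 following laps, >100%
  amplitude increase), field width, COM shift, and goal-referenced
  selectivity (G−S)/(G+S);
- **vm**: intracellular V_m processing (spike stripping,
  threshold-based trial baseline correction, plateau-potential
  detection) and decomposition of the reward-switch ΔV_m into goal- and
  space-referenced areas, with
  `Index = (Area_Goal − Area_Space)/(Area_Goal + Area_Space)`,
  a symmetry score, and a reconstruction check;
- **spacetime**: space-map vs time-map peaks across running-speed
  terciles, dissociating spatial from temporal coding;
- **simulate**: a synthetic-data generator (behavior, calcium, V_m)
  with known ground truth — cell categories, field anchors, injected
  plasticity events, true goal/space weights — so every stage has a
  recovery test without any external data.

## Worked example

```python
from placeref.config import SimConfig
from placeref.simulate import simulate_behavior_full, simulate_calcium
from placeref.pipeline import (
    compute_dff_matrix, identify_stage, classify_stage, pv_stage,
)

cfg = SimConfig(n_cells=60, n_laps_pre=40, n_laps_post=40, seed=7,
                fractions={"space": 0.3, "goal": 0.3, "intermediate": 0.4})
session, schedule = simulate_behavior_full(cfg)
raw_f, truth = simulate_calcium(cfg, session, schedule)

dff_mat, _ = compute_dff_matrix(raw_f)
pre, post, _ = identify_stage(dff_mat, session, n_shuffles=200, seed=0)
table, fractions = classify_stage(pre, post, session)
print("place cells pre/post:", int(pre.table.is_place_cell.sum()),
      "/", int(post.table.is_place_cell.sum()))
print("category fractions:", {k: round(v, 3) for k, v in fractions.items()})
pv = pv_stage(pre, post)
print("space similarity: %.3f   goal similarity: %.3f"
      % (pv["space_similarity"], pv["goal_similarity"]))
```

prints

```
place cells pre/post: 55 / 58
category fractions: {'space': 0.264, 'goal': 0.34, 'intermediate': 0.396}
space similarity: 0.197   goal similarity: 0.172
```

Of 60 simulated cells, 55/58 pass the place-cell criteria per
condition; the recovered category fractions sit within sampling error
of the generated 0.3/0.3/0.4; and the pre-vs-post population-vector
similarities are low and balanced, as expected for a mixed cohort
(a pure-goal cohort drives goal similarity above 0.8 and space
similarity to ~0).

## Command line

```bash
placeref simulate --config cfg.yaml --out session.h5 --seed 1
placeref all --in session.h5 --out results/
placeref classify --in session.h5 --out results/   # single stage
```

Outputs: place-cell tables, a classification CSV, PV matrices, a BTSP
event table, V_m decomposition JSON, per-stage CSVs and a
`summary.json`; `params.json` logs every parameter used.

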