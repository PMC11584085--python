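# mazeplan

Planning models for search in partially observable grid mazes. An agent
must find a hidden exit that is equally likely to be under any tile of the
maze's *rooms* — clusters of hidden tiles revealed all at once when any of
them enters the agent's line of sight. The package provides:

- **`maze_world`** — maze geometry, corner-discretized line-of-sight
  (isovists), BFS shortest paths, room-revelation mechanics, validation,
  and two text file formats (ASCII grid + YAML sidecar, or a single
  structured YAML file).
- **`decision_tree`** — the observation-order decision tree: each node is a
  vantage tile plus the set of rooms observed so far, with statistics
  `s` (steps from the parent vantage), `e` (mean distance to a newly
  revealed tile), `p` (chance the exit is revealed here) and `cells`.
  Equal subproblems are shared, so the structure is a DAG.
- **`planners`** — cost models over the tree: optimal expected-utility
  planning (EU), discounted planning (DU, rate γ), probability-weighted
  planning (PW, π(p)=exp(−|ln p|^β)), their combination (PW-DU), bit-limited
  numerosity variants (EU-Num, DU-Num, …), a Monte Carlo tree search
  approximation (Sampling), myopic heuristics (Steps, Cells, Steps-Cells,
  Random, and -Num variants), a temperature-τ softmax choice rule, and a
  generative agent simulator.
- **`numerosity`** — a capacity-limited perception channel mapping counts
  n ∈ [1, 80] to expected subjective estimates q(n, B), built by
  rate–distortion alternating minimization under a Zipfian prior with at
  most B bits of mutual information.
- **`fitting`** — individual-level grid-search fitting by fivefold
  cross-validated penalized likelihood (1/τ prior on the softmax
  temperature), model ranking by total test log-likelihood, per-individual
  planner-vs-heuristic family comparison, aggregate first-choice
  frequencies, and participant-level bootstrap correlations.
- **`decision_times`** — OLS regressions of initial and subsequent decision
  times on fitted parameters (τ; τ, γ; τ, γ, B; τ, γ, b=|β−1|).
- **`synthetic_data`** — a rejection-sampling maze generator, hand-coded
  fixture mazes whose decision structure discriminates between model
  families (verified at load), and synthetic cohorts with known generating
  parameters and linear-plus-noise decision times.
- **`pipeline_io` / `cli`** — configuration, manifests, seed fan-out, and
  the end-to-end pipeline.

## CLI

```sh
mazeplan maze validate long_compact        # check a fixture or maze file
mazeplan maze tree long_compact            # export its decision tree (TSV)
mazeplan simulate --config cfg.yaml --seed 1 --out run/
mazeplan fit      --log run/decisions.tsv --mazes run/mazes --models EU,DU --out fits/
mazeplan compare  --log run/decisions.tsv --mazes run/mazes --models EU,DU,Steps,Random --out cmp/
mazeplan correlate --log run/decisions.tsv --mazes run/mazes --out corr/
mazeplan regress  --log run/decisions.tsv --mazes run/mazes --models EU,DU --out reg/
mazeplan recover  --seed 1 --out rec/      # end-to-end γ-recovery study
```

A simulate config is YAML; unknown keys are rejected:

```yaml
n_participants: 20
mazes: {kind: generated, n: 12, n_rooms: [4, 6]}
mixture: {DU: 1.0}
params:
  DU: {tau: [0.5], gamma: [0.2, 0.5, 0.8]}
time:
  initial: {const: 3200, tau: -250, gamma: 500}
  subsequent: {const: 900, tau: 60, gamma: -130}
  noise_sd: 400
```

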