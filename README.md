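# labopt

Deterministic batch Bayesian optimization of laboratory protocols, with a
simulated cloud-lab harness so everything is testable at the desk.

The core algorithm grows a hierarchical trisection tree over the scaled
search space. A Gaussian-process surrogate (Matérn-5/2 kernel) attaches an
upper confidence bound (UCB) to every unmeasured box center, and each
experiment batch is drawn from the *frontier*: the upper convex hull of the
(tree depth, UCB) scatter of unevaluated leaves. Shallow hull points explore
large unknown regions, deep hull points exploit the neighborhood of the
incumbent, and the first request of every batch is exactly what a serial run
would have asked for — so batching up to the lab's parallelism level `k`
never changes the serial algorithm's convergence behavior. The loop is fully
deterministic: identical inputs give byte-identical run histories.

## Layout

| module | what it does |
|---|---|
| `labopt.partition` | trisection tree over the unit hypercube |
| `labopt.surrogate` | GP posterior/UCB queries, marginal-likelihood refits |
| `labopt.frontier` | upper convex hull of (depth, UCB); batch filling |
| `labopt.optimizer` | the three-step main loop, batch dispatch, replay |
| `labopt.space` | native parameters ↔ unit hypercube; one-use candidate assignment |
| `labopt.objectives` | endpoint scaling, combined scores, chromatogram resolution |
| `labopt.baselines` | batch GP optimization (TS/EI/PI/UCB), random, Latin hypercube |
| `labopt.simlab` | k-slot virtual job queue replaying tabulated datasets |
| `labopt.fixtures` | synthetic sweep tables and peak lists with answer keys |
| `labopt.state` | save-state suggest → run-in-lab → ingest workflow |
| `labopt.cli`, `labopt.reporting` | command line, run logs, diagnostics |

## CLI

Closed-loop run against a replayed dataset (generate one first):

```bash
labopt fixtures sweep --grid 5,4,3,2 --family bowl --seed 1 --out fx
labopt run --dataset fx/dataset.csv --objective height --method fbo \
    -k 4 --budget 25 --out results/run
```

`--method` selects the frontier-batch optimizer (`fbo`) or a comparison
strategy (`ts`, `ei`, `pi`, `ucb`, `random`, `lhs`). Artifacts are plain
text: `history.csv`, `best_so_far.csv`, `tree.json`, `frontier_log.csv`,
`summary.json`.

The built-in 1-D multimodal test function:

```bash
labopt run --objective sinusoid --budget 50 -k 4 --out results/sin
```

Repeated baseline studies:

```bash
labopt baseline --dataset fx/dataset.csv --objective height \
    --acquisition ei --batch 4 --budget 25 --repeats 100 --seed 0 --out results/ei
```

Driving a real lab through a save-state file:

```bash
labopt suggest --space space.yaml --state state.yaml -k 3 --budget 18
# ... run the printed configurations in the lab, collect results.csv ...
labopt ingest --state state.yaml --results results.csv
labopt suggest --state state.yaml   # next batch
```

`suggest` replays the deterministic algorithm against the results recorded
so far, so the state file needs to store nothing but the problem definition
and the result ledger. Results uploaded for configurations that were never
suggested are accepted as historical data: they condition the surrogate but
the tree still starts from the center of the space.

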