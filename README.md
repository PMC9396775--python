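# abfold

2D AB off-lattice protein folding by hybrid particle-swarm / tabu-search
energy minimization.

Chains over the two-letter alphabet {A, B} (A hydrophobic, B hydrophilic)
are folded in the plane as unit-bond chains parameterized by their n−2
signed bend angles. The potential energy is the Stillinger-type AB
off-lattice form

    E = Σ (1/4)(1 − cos αᵢ)  +  Σ_{j ≥ i+2} 4 (r_ij⁻¹² − C(ηᵢ, ηⱼ) r_ij⁻⁶)

with C = (1 + ηᵢ + ηⱼ + 5 ηᵢ ηⱼ)/8 (1 for AA, ½ for BB, −½ for mixed
pairs). The global minimum is sought three ways:

- **pso** — particle swarm optimization (260 particles, linearly decaying
  inertia, velocity clamping, toroidal angle space);
- **tabu** — tabu search with single-coordinate neighborhood moves of
  magnitude π·Q·K, a candidate set of the L_C best of L neighbors, a FIFO
  tabu list with tenure L_T, an energy+distance tabu criterion and a
  better-than-incumbent aspiration rule;
- **hybrid** — PSO runs until its best energy genuinely stalls (no
  improvement > 1e−4 over 150 iterations), then its global best seeds a
  tabu refinement with the remaining iteration budget (800 total by
  default).

Benchmarks are the standard Fibonacci AB sequences (S₀ = "A", S₁ = "B",
S_{k+1} = S_{k−1} + S_k) of lengths 13, 21, 34 and 55.

## CLI

```sh
# benchmark sequence as FASTA
abfold generate --length 13 --out fib13.fasta

# evaluate a conformation (angles CSV: header "index,angle_rad")
abfold energy --seq fib13.fasta --angles angles.csv

# minimize; writes a JSON run report, optionally coordinates CSV / CA-only PDB
abfold minimize --seq fib13.fasta --method hybrid --seed 1 \
    --out run.json --coords-out coords.csv --pdb-out chain.pdb

# all methods over seeds 0..9, summary table with improvement percentages
abfold compare --seq fib13.fasta --seeds 10 --out table.csv

# exhaustive grid minimum on tiny chains (test oracle; n <= 6)
abfold oracle --seq aaa.fasta --step 0.01
```

Runs are deterministic given `--seed`; a run report echoes its full
configuration and can be replayed exactly (`abfold.io.config_from_dict`).
YAML config files mirror the flag names (`pso:` / `tabu:` sections);
unknown keys are rejected. Defaults follow the published benchmark
parameters: 260 particles, 800 iterations, λ₁ = λ₂ = 2.0, K = 0.93,
L = 40, L_C = 6, L_T = 8, E₀ = 0.10, r₀ = 0.005.

### Handoff policy

The PSO phase may use the whole iteration budget but surrenders the
remainder to tabu search as soon as it has genuinely converged. On these
landscapes PSO keeps making small improvements late into the run (its
shrinking inertia makes it an increasingly local searcher), while the
tabu neighborhood — single-coordinate moves — excels at escaping stalls
but not at coordinated fine refinement; cutting PSO off at a fixed
fraction of the budget measurably hurts both phases.

## Layout

| module | contents |
| --- | --- |
| `abfold.model` | sequences, conformations, chain geometry, energy |
| `abfold.sequences` | Fibonacci benchmark generator, FASTA I/O |
| `abfold.pso` | particle swarm optimizer |
| `abfold.tabu` | tabu search |
| `abfold.hybrid` | hybrid driver, baselines, run summaries |
| `abfold.oracle` | independent brute-force energy + grid minimizer (test oracle) |
| `abfold.io` | run reports (JSON), CSV tables, PDB export, YAML config |
| `abfold.cli` | `abfold` command-line entry point |
| `abfold.viz` | optional matplotlib conformation plots |
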