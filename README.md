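# bethe-rda

A stochastic cellular automaton ("random domino automaton", a forest-fire
type model) on the Bethe lattice with coordination number 3, together with
the analytic machinery that makes it solvable:

* **`bethe_rda.core`** — domain types and the exact tree combinatorics:
  cluster perimeter `i(k-2)+2`, the complete cell-type census of an empty
  cluster from its size and creating-cell count, and the change of
  variables between per-type empty-cell counts `x0..x3` and the aggregates
  `{rho, n0, n1_0, nhat0}`.
* **`bethe_rda.steady`** — residuals of the seven stationary balance laws
  for a general avalanche law, and the complete solver for the solvable
  law `mu_i = delta / i`: linear elimination of `x(n, rho)`, intersection
  of the resulting two conics, admissibility filtering, and the stability
  window `(delta_min, delta_max)` plus the `n = n0` crossover located by
  continuation and bisection.
* **`bethe_rda.distribution`** — the cascade equations for the
  cluster-size distribution `n_i` (single/double/triple convolutions for
  the enlarging and two merging channels), truncation diagnostics, the
  exact geometric closed form when merging is off, tail-slope estimation,
  and the inverse problem `mu_i <- n_i`.
* **`bethe_rda.recurrences`** — exact-integer Motzkin and
  generalized-Motzkin (OEIS A036765) recurrences, and the rescaling that
  maps cascade output onto them, including the limit bookkeeping that
  shows when exact inverse-power solutions are (un)reachable.
* **`bethe_rda.simulate`** — Monte-Carlo realization on finite 3-regular
  lattices (uniform random regular graph, or a ball of the actual tree for
  exact per-snapshot combinatorial checks), with incremental union-find
  cluster tracking and batch-means error estimation.
* **`bethe_rda.cli`** — the `rda` command.

## CLI

```sh
# stationary state for given occupation probabilities and delta
rda solve --c0 1 --c1 0.5 --c2 0.25 --c3 0.125 --delta 0.28 --json state.json

# stability window in delta and the n = n0 crossover
rda range --c0 1 --c1 0.5 --c2 0.25 --c3 0.125

# cluster-size distribution (TSV: i, n_i per 1e6 cells)
rda dist --c0 1 --c1 0.5 --c2 0.25 --c3 0.125 --delta 0.28 --imax 10000 --tsv dist.tsv

# integer sequences
rda recur --sequence a036765 --terms 13

# Monte-Carlo run on a 50k-cell random 3-regular graph
rda simulate --mode random-regular --cells 50000 --c0 1 --c1 0.5 \
    --c2 0.5 --c3 0.5 --delta 0.5 --seed 42 --json sim.json
```

`rda solve` exits with status 2 when no stationary state exists, naming
the admissibility test that failed (`n <= 0 branch` below the window,
`x2 <= x0` above it).

## Known model-vs-realization caveats

The analytic solution reproduces the mean-field balance equations exactly
(validated against an independent unreduced-system solve in exact rational
arithmetic). Two caveats are deliberate and documented in the test suite:

* A handful of printed reference-table cells are internally inconsistent
  with the model's own equations (solver noise / misprints in the source
  tables); the corresponding acceptance checks fail honestly.
* Monte-Carlo runs agree with the mean-field solution only approximately:
  the closure neglects type/size correlations, and above the
  site-percolation threshold `rho = 1/2` of the 3-regular lattice a giant
  cluster repeatedly forms and collapses, which the stationary mean-field
  picture cannot represent. The simulator itself is validated exactly
  against a brute-force Markov-chain enumeration on a small lattice, and
  the cycle-free combinatorial identities hold exactly on tree snapshots.
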