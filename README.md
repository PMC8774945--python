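# qsdlearn

Learning quasi-stationary distributions (QSDs) of absorbing finite-state
Markov chains with an average-reward actor-critic method, alongside exact
eigenvector solvers and the classical simulation baselines.

A strictly sub-Markovian kernel `K` loses probability mass to an absorbing
cemetery state. Its QSD — the long-run law conditioned on survival — is the
normalised principal left eigenvector of `K`, and equivalently the unique
distribution `alpha` that is stationary for the *regenerative* kernel
`K_alpha(x,y) = K(x,y) + (1 - K(x,E)) alpha(y)` that restarts from `alpha`
upon absorption. `qsdlearn` parameterises the candidate `alpha` as a softmax
over states and maximises the (nonpositive) KL divergence rate between the
path laws of `K_alpha` and `K_beta` (`beta = alpha K_alpha`), which is zero
exactly at the QSD. The gradient is estimated from sampled transitions via
a policy-gradient theorem with a learned tabular value function and running
reward estimate — the "ac-alpha" actor-critic.

## Contents

| module | what it provides |
| --- | --- |
| `chain_core` | `SubMarkovKernel`, `Distribution`, `RegenerativeKernel`; exact QSD / stationary solvers, transition sampling, exact KL rate |
| `model_zoo` | loopy chain, absorbed M/M/1/N queue (constant or state-dependent drift), SIS-style extinction chain, random instances |
| `rl_objective` | softmax policy, reward, exact average reward / value function, analytic policy gradient + finite-difference oracle |
| `actor_critic` | the actor-critic loop: TD error, simultaneous theta/psi/r updates, batch chains with warm start |
| `baselines` | single-particle empirical scheme, projected stochastic approximation, Polyak averaging, Fleming–Viot particles, simplex projection |
| `experiments` / `cli` | experiment driver, trace CSVs, `qsd` command line |
| `benchmarks` | the two canonical M/M/1/500 queue runs |

## Command line

```sh
# exact QSD of the absorbed M/M/1/500 queue, written as single-column text
qsd exact --model mm1 --N 500 --rho 1.25 --out qsd.txt

# actor-critic on the 3-state loopy chain at the benchmark settings
qsd fit ac --model loopy --eps 0.1 --iters 20000 --batch 4 \
    --lr-theta fpow:0.1,0.2 --theta0 ramp:-1,1 --seed 0 --out run/

# baselines: vanilla | projection | polyak | fv
qsd fit vanilla --model loopy --eps 0.1 --episodes 10000 --out run_v/
qsd fit fv --model loopy --eps 0.1 --particles 1000 --steps 2000 --out run_fv/

# export a kernel matrix; load it back anywhere with --kernel FILE
qsd model export --model sis --N 20 --beta 2 --gamma 1 --out sis.tsv

# log-log error curves from trace CSVs
qsd plot --trace run/trace_seed0.csv --out error.png
```

Learning-rate/step specs are `const:c`, `pow:r` (`t^-r`) or `fpow:r,c`
(`max(t^-r, c)`). Every run writes one `trace_seed<k>.csv` per seed
(columns `iteration,l2_error,r_est,kl_rate`, full config embedded in the
header) plus a `summary.json`.

For kernels where only a few states can absorb (e.g. the queue, which leaks
only from the bottom level), pass `--source-state 1` to sample every batch
transition from that state — transitions out of non-absorbing states carry
zero reward and zero gradient, so free-running chains provide no signal.

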