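# obpcnet

Inferring **relative synaptic coupling strengths** between two
reciprocally connected brain regions — the olfactory bulb (OB) and the
anterior piriform cortex (PC) — from easy-to-measure spike statistics.

Dual-array recordings from OB and PC constrain twelve robust
relationships among population-averaged statistics (firing rate ν,
spike-count variance and covariance, Fano factor FF = Var/mean, and
pairwise count correlation ρ), compared between regions and between the
spontaneous and odor-evoked states (e.g. ν_PC < ν_OB in both states,
FF_PC^Sp > FF_PC^Ev, ρ_PC^Sp > ρ_PC^Ev).  This package determines which
couplings are compatible with all twelve.

## What's inside

- **`rate_model`** — a minimal 6-population stochastic (Wilson–Cowan)
  model of the coupled circuit,
  `τ dx_j = (−x_j + μ_j + Σ_k g_jk F(x_k)) dt + σ_j dW_j` with
  `ν_j = F(x_j)`, sigmoid `F(X) = (1 + tanh((X−0.5)/0.1))/2`, and noise
  correlated within but not across regions; plus a seeded
  Euler–Maruyama Monte Carlo sampler.
- **`moment_closure`** — a fast self-consistent Gaussian closure for the
  18 stationary statistics (means, variances, within-region
  covariances) and the derived firing-rate statistics; replaces Monte
  Carlo during parameter exploration.
- **`constraints`** — the twelve strict inequalities, evaluated on any
  model's population summaries.
- **`sweep`** — exhaustive classification of the 4-D coupling space
  (|gIO|, gEO, |gIP|, gEP over 0.1–2.0), Monte Carlo validation of the
  admissible set, per-constraint profiles, constraint-subset analyses,
  and SVD structure of the admissible tuples.
- **`spike_stats`** — windowed spike-count statistics from rasters
  (half-overlapping windows, pooled across trials), raster-processing
  rules, and a seeded generator of correlated Poisson trains.
- **`lif_network`** — a 200-neuron conductance-based
  leaky-integrate-and-fire model of the same circuit (Erdős–Rényi
  graphs, delayed cross-region excitation, log-normal thresholds) that
  verifies the inferred coupling ordering and runs targeted violation
  experiments.
- **`workbench`** + the `obpcnet` CLI — YAML-configured end-to-end
  experiments with checkpointing and report export.

## Worked example

Solve one coupling tuple in both activity states and check the twelve
constraints:

```python
from obpcnet import CouplingTuple, table2_spec, solve_moments, evaluate_table1
from obpcnet.sweep import region_summaries

ct = CouplingTuple(gIO=0.25, gEO=1.0, gIP=1.0, gEP=1.25)
reports = {}
for state in ("spontaneous", "evoked"):
    r = solve_moments(table2_spec(state, ct), coupling=ct)
    reports[state] = r
    print(f"{state}: {r.status} in {r.n_iter} iterations")
    print("  mean rates E[F(x_j)]:", r.rate_stats.mean.round(4))

sp_ob, sp_pc = region_summaries(reports["spontaneous"], "spontaneous")
ev_ob, ev_pc = region_summaries(reports["evoked"], "evoked")
rep = evaluate_table1(sp_ob, sp_pc, ev_ob, ev_pc)
print("all 12 constraints satisfied:", rep.all_satisfied)
print(f"OB rate sp->ev: {sp_ob.rate:.4f} -> {ev_ob.rate:.4f}")
print(f"PC rho  sp->ev: {sp_pc.rho:.4f} -> {ev_pc.rho:.4f}")
```

prints

```
spontaneous: converged in 17 iterations
  mean rates E[F(x_j)]: [0.6241 0.3029 0.2912 0.5758 0.2396 0.2323]
evoked: converged in 14 iterations
  mean rates E[F(x_j)]: [0.6926 0.3515 0.3268 0.5971 0.2349 0.2277]
all 12 constraints satisfied: True
OB rate sp->ev: 0.4060 -> 0.4570
PC rho  sp->ev: 0.1675 -> 0.1657
```

so this tuple is *admissible*: firing rates are higher in OB than PC and
rise with the stimulus, and PC pairs decorrelate in the evoked state
(ρ drops from 0.1675 to 0.1657), among the other relationships.
Sweeping all tuples on a step-0.25 grid,

```bash
obpcnet sweep run --step 0.25 --out sweep.csv   # ~1 minute
obpcnet sweep svd --table sweep.csv
```

classifies 4096 tuples, of which ≈ 1.4% are admissible; the mean signed
admissible tuple is ≈ (gIO, gEO, gIP, gEP) = (−0.60, 1.13, −1.52, 1.30)
and the top two SVD dimensions carry ≈ 81% of its variance.  Every
admissible tuple has |gIP| > |gIO|, and on average
|gIO| < gEO < gEP < |gIP|: inhibition within the cortex must be strong,
inhibition within the bulb weak, and cortical feedback stronger than the
feed-forward projection.

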