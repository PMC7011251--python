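# emergebayes

Bayesian analysis of interval-censored time-to-event data from plant
phenotyping experiments — seedling emergence, germination, flowering, or
any trait where each individual's event time is known only up to the
imaging interval in which it happened, and some individuals never show the
event at all.

The typical user has trays of seeds photographed on a fixed cadence (say,
every 2 h for 12 days) and wants answers to questions such as *"do primed
seedlings emerge earlier than the controls?"* or *"what is the probability
that compound E increases emergence yield by at least 5% relative to
compound F?"*. Classical tray-level t-tests on fitted curve parameters
cannot answer the second question at all, and their power does not depend
on the number of seeds per tray; this package's posterior does both.

## Model

Each seed is viable with probability α (the **emergence yield**); a
non-viable seed never emerges. A viable seed's emergence time follows the
Gompertz (Gumbel-minimum) distribution

    F(t) = exp(−exp(−B (t − C)))

with **uniformity** B (1/day, steepness of the emergence wave) and
**half-time** C (days, location; F(C) = 1/e). For a tray observed on the
grid t₀ < t₁ < … < t_T, with N_i seeds emerging in [t_i, t_{i+1}) and M
seeds never seen to emerge, the likelihood is

    L(α, B, C) = [1 − α F(t_T)]^M · ∏_i [α (F(t_{i+1}) − F(t_i))]^{N_i}

Priors: α ~ Beta(a, b); B and C ~ Gaussians truncated to (0, ∞) (defaults
Beta(1, 9), B ~ N(2, 0.5²), C ~ N(5, 2²), all configurable). The posterior
is sampled by an in-repo adaptive random-walk Metropolis sampler and
validated against deterministic grid integration. Treatment questions are
answered by pairing draws from two groups' posteriors and counting.

## Worked example

```python
from emergebayes import (ModelParams, PriorSpec, SamplerConfig, fit_mcmc,
                         simulate_tray, prob_param_less, summarize,
                         mc_standard_error)

prior = PriorSpec()
control = simulate_tray(ModelParams(0.93, 1.65, 4.27), seed=1, label="control")
primed  = simulate_tray(ModelParams(0.98, 1.19, 4.11), seed=2, label="primed")

fits = {name: fit_mcmc(data, prior, SamplerConfig(seed=3))
        for name, data in [("control", control), ("primed", primed)]}

print(summarize(fits)[["alpha_mean", "B_mean", "C_mean", "C_ci_lo", "C_ci_hi"]]
      .to_string(float_format=lambda x: f"{x:.3f}"))

p = prob_param_less(fits["primed"], fits["control"], "C", n_pairs=1000, seed=4)
print(f"P(C_primed < C_control) = {p:.3f} +/- {mc_standard_error(p, 1000):.3f}")
```

prints

```
         alpha_mean  B_mean  C_mean  C_ci_lo  C_ci_hi
group
control       0.866   1.796   4.304    4.193    4.422
primed        0.916   1.130   4.156    3.982    4.333
P(C_primed < C_control) = 0.896 +/- 0.010
```

Each tray is 110 simulated seeds observed every 2 h for 12 days. The
posterior mean of C recovers the generating half-times (4.27 and 4.11
days) and the 95% credible intervals quantify how precisely one tray pins
them down; the last line is the posterior probability that the primed
group emerges earlier, with its Monte-Carlo standard error over the 1000
paired draws. (The yield posteriors sit slightly below the generating
values because the default Beta(1, 9) prior is centred at 0.1; pass
`--prior-alpha` / `PriorSpec(alpha_a=..., alpha_b=...)` to change it.)

The same pipeline is available from the shell:

```sh
emergebayes simulate --out trays/ --seed 1
emergebayes fit trays/control_water.csv --out posteriors/control.csv --seed 2
emergebayes fit trays/A_water.csv --out posteriors/A.csv --seed 3
emergebayes compare posteriors/A.csv posteriors/control.csv --param C --seed 4
emergebayes summarize posteriors/*.csv --out summary.csv
```

`simulate` writes 16 reference trays (control and seven priming compounds,
each in water and 150 mM NaCl); `fit` writes a posterior archive (draws
CSV + JSON sidecar with seeds and convergence diagnostics) and a curve
ensemble plot.

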