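# Study configuration: likelihood data plus the ordered analysis suite.
# Equivalent to linkprev.runner_report.paper_preset().
#
# data:      counts the Bernoulli likelihood conditions on (completer cohort)
# analyses:  engine is "frequentist", "closed_form", or "mcmc" (with settings);
#            prior is "flat", {n, k} (elicited as alpha=k+1, beta=n-k+1),
#            or {alpha, beta} explicit.
master_seed: 123
level: 0.95
data:
  source: self-report completers
  n: 549
  k: 311
analyses:
  - name: Frequentist
    engine: frequentist
  - name: Non-informative
    prior: flat
    engine: mcmc
    mcmc: {chains: 4, iterations: 20000, warmup: 500, thin: 5, seed: 123}
  - name: Primary
    prior: {n: 1061, k: 632}
    engine: mcmc
    mcmc: {chains: 4, iterations: 20000, warmup: 500, thin: 5, seed: 123}
  - name: Sensitivity 1
    prior: {n: 2369, k: 1394}
    engine: mcmc
    mcmc: {chains: 4, iterations: 20000, warmup: 500, thin: 5, seed: 123}
  - name: Sensitivity 2
    prior: {n: 3430, k: 2026}
    engine: mcmc
    mcmc: {chains: 4, iterations: 20000, warmup: 500, thin: 5, seed: 123}
  - name: Sensitivity 3
    prior: {n: 1061, k: 632}
    engine: mcmc
    mcmc: {chains: 2, iterations: 50, warmup: 10, thin: 1, seed: 123}
  - name: Sensitivity 4
    prior: {n: 1061, k: 632}
    engine: mcmc
    mcmc: {chains: 4, iterations: 40000, warmup: 600, thin: 10, seed: 123}
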