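# areabayes

Bayesian inference of **geographic contact areas** from categorical trait
data. Given a set of entities with locations, optional family labels and a
matrix of categorical features (the motivating case: languages coded for
typological features), `areabayes` finds groups of entities whose shared
traits are *not* explained by two confounders — universal preference for a
trait state, and inheritance within a family — and are therefore evidence
of horizontal transfer (contact). The approach carries over to other
spatial clustering problems with categorical data and known confounders.

## Model

Each cell (entity `l`, feature `f`, observed state `s`) follows a mixture
of three categorical distributions:

    P(X_lf = s) = w_u,f α_{f,s} + w_i,f β_{f,φ(l),s} + w_c,f γ_{f,Z(l),s}

- `α_f` — universal preference over the states of feature `f`,
- `β_{f,φ}` — inheritance within family `φ`,
- `γ_{f,k}` — contact within area `Z_k`, a latent entity subset,
- `w_f` — per-feature mixture weights on the simplex; the contact
  (inheritance) weight is re-normalized away for entities in no area
  (no family).

Priors: Dirichlet on every weight triple and probability vector (uniform
by default, or pseudocounts `ψ_n = 1 + μ_n ρ` from an empirical sample); a
geo-prior on each area that decays exponentially with the mean edge cost
of its minimum-spanning-tree linkage (`log P ∝ −λ c_k`), truncated to
disjoint configurations; and a uniform prior on area sizes within bounds.
Inference is Metropolis–Hastings over `{Z, w, α, β, γ}` with Dirichlet
proposals for simplex parameters and spatially informed grow/shrink/swap
moves for areas. The number of areas `K` is chosen by scanning and
comparing the deviance information criterion (DIC). See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

Simulate a dataset with one planted family and a weaker planted contact
area, then let the sampler recover the area while the family is modelled:

```python
import numpy as np
from areabayes import SamplerConfig, run_chain, membership_frequencies
from areabayes.benchmarks import confounder_separation_benchmark

bench = confounder_separation_benchmark(seed=3)
trace = run_chain(
    bench.dataset, bench.priors, 1,
    SamplerConfig(n_steps=300_000, n_retained=1000, seed=7),
)
freq = membership_frequencies(trace)[0]          # per-entity frequencies
consensus = set(np.flatnonzero(freq > 0.5))
planted = bench.synth.areas[0]
print(f"planted area recovered: {len(consensus & planted)}/{len(planted)}")
print(f"acceptance rates: { {op: f'{a/p:.0%}' for op, (p, a) in trace.acceptance.items()} }")
```

Typical output:

```
planted area recovered: 12/12
acceptance rates: {'area': '7%', 'weights': '58%', 'alpha': '25%', 'beta': '54%', 'gamma': '55%'}
```

All twelve planted members end at posterior membership frequency near 1:
their shared low-entropy states sit on states the confounders dis-prefer,
so the contact component is the only credible explanation. The 20-member
family, although more internally homogeneous than the area, is *not*
reported as contact — its similarity is absorbed by the inheritance
component β.

The same workflow is available from the shell:

```bash
areabayes simulate --experiment exp2 --seed 3 --output sim/
areabayes run      --config run.yaml          # single K
areabayes scan-k   --config scan.yaml         # DIC over a K list
areabayes summarize out/summary.json
```

where the YAML config names the dataset files, priors, sampler settings
and `K` (see `areabayes.config`). Each run writes a samples file, an area
membership file, a JSON summary (membership frequencies, area ranks,
Gabriel-graph edges, diagnostics) and a manifest that reproduces the run
bit-identically.

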