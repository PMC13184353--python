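# apathynet

Symptom-level psychometrics of apathy questionnaires: latent-factor
analysis with a factor-purity index, absolute-Spearman symptom networks
with modularity-based community detection and restart-stability selection,
and a Gaussian sliding-window scan of module structure across the adult
lifespan.

## The scientific problem

Apathy — diminished goal-directed behaviour — is usually decomposed into
behavioural, cognitive and emotional dimensions. Whether *social* apathy
(loss of motivation to engage with other people) is a separable dimension
or a by-product of general loss of initiative is an open question with
direct consequences for diagnostic criteria. The question is psychometric:
if social items consistently cluster together, and segregate from
non-social items, across factor models, symptom networks and the lifespan,
social apathy stands as its own dimension.

`apathynet` implements that analysis battery for item-level data from
three self-report instruments — the Apathy Motivation Index (AMI, 18
items), Apathy Evaluation Scale (AES, 18 items) and Dimensional Apathy
Scale (DAS, 24 items), all on a 0–4 ordinal scale — and ships a synthetic
cohort generator so every stage runs end to end without participant data.

## The methods

**Exploratory factor analysis** (`apathynet.efa`). KMO sampling adequacy,
Bartlett's sphericity test, Kaiser retention (eigenvalues > 1),
maximum-likelihood extraction via the concentrated likelihood in the
uniquenesses, varimax/promax rotation. The model test is
χ² = (n − 1 − (2p+5)/6 − 2k/3)·F_min with df = ((p−k)² − (p+k))/2.
The **factor purity** of item *i* with designated factor *d* is

    purity_i = λ²_{id} / Σ_f λ²_{if}  ∈ [0, 1],

the share of the item's communality owned by its designated factor; factor
means are compared by one-way ANOVA plus a planned one-sided Welch test.

**Confirmatory factor analysis** (`apathynet.cfa`). The a-priori
three-factor AMI model (Behavioural/Social/Emotional; items AMI-2, AMI-6,
AMI-8 excluded, 15 indicators, df = 87) fitted by minimising the ML
discrepancy F = ln|Σ̂| + tr(SΣ̂⁻¹) − ln|S| − p with analytic gradients,
reported with CFI, TLI, RMSEA (90% CI by noncentral-χ² root finding) and
SRMR.

**Symptom networks** (`apathynet.network`). Nodes are items; edges are
absolute Spearman correlations |ρ|. Community structure maximises
weighted modularity

    Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j)

with a seeded Louvain algorithm; the most frequent canonical partition
over many random restarts (the *modal partition*) is analysed, with its
restart share as a stability measure. Modules are summarised by domain
purity (fraction of members sharing the modal a-priori domain) and central
node (highest intra-modular strength). The |ρ| ≥ 0.1 sparsification is
used only for GraphML export.

**Lifespan scan** (`apathynet.lifespan`). A 10-year window slides in
1-year steps; participants are weighted by a Gaussian kernel (σ = 5 years,
truncated at ±5). Windows with Kish effective sample size (Σw)²/Σw² below
30 are excluded; each included window gets a weighted-Spearman network, a
modal partition and module summaries. Module purities feed a Group ×
Domain two-way ANOVA (Type II), and an assessment-mode sensitivity split
re-runs the network pipeline per mode.

**Synthetic cohorts** (`apathynet.simulate`). Ordinal responses from a
correlated latent-factor model: y = Λf + ε with f ~ N(0, Φ), thresholds at
the standard-normal quintiles; block simple structure, per-participant
ages and cohort/mode labels, optional age-band model mixtures for
non-stationary lifespan tests.

## Worked example

```python
import apathynet as an

ami = an.builtin_scale("AMI")
model = an.scale_factor_spec(ami, within_load=0.7, between_corr=0.3)
ds = an.simulate_cohort(an.CohortSimSpec(n=4000, model=model, seed=42))

net = an.spearman_network(ds)
census = an.stable_partition(net, n_restarts=1000, seed=0)
print(f"modal partition share: {census.modal_share:.3f} "
      f"({census.modal.n_communities} modules, Q = {an.modularity(net, census.modal):.3f})")
for mod in an.summarise_modules(net, census.modal):
    print(f"  {mod.modal_domain:<12} purity {mod.purity:.2f}  "
          f"central node {mod.central_node}  members {len(mod.members)}")
```

prints

```
modal partition share: 1.000 (3 modules, Q = 0.252)
  Emotional    purity 1.00  central node AMI-16  members 6
  Social       purity 1.00  central node AMI-2  members 6
  Behavioural  purity 1.00  central node AMI-5  members 6
```

All 1000 Louvain restarts find the same three-module partition (share
1.000), the modules coincide exactly with the a-priori AMI domains (purity
1.00), and each module's most strongly intra-connected item is reported as
its central node. On the same cohort, `an.run_efa(ds, k=3)` reports
KMO = 0.90 and promax inter-factor correlations ≈ 0.3, matching the
generating model.

The same stages are available from the shell:

```sh
apathynet simulate --n 4000 --outdir out
apathynet network --input out/dataset.csv --scale AMI --n-restarts 1000 --outdir out
apathynet run config.yaml        # full staged pipeline with manifest
```

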