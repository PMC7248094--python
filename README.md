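# qmanifold

Information-geometric exploratory analysis of categorical questionnaire
data. Built for survey researchers, epidemiologists and social scientists
who group respondents (by region, ethnicity, exposure, any categorical
covariate) and want a low-dimensional map of how the groups' *response
distributions* relate — a group-level counterpart of PCA that respects the
statistics of categorical data instead of ad-hoc encodings.

## The method

A questionnaire with `N_Q` categorical questions defines a probability
distribution over response strings `I` (one respondent's ordered answers).
Each group `k` of respondents is identified with its distribution `p_I^k`.
In square-root coordinates

    ξ_I = √p_I ,      Σ_I ξ_I² = 1,

every group is a unit vector on the positive quadrant of a hypersphere, and
the Fisher-information distance between two groups is the great-circle arc
length

    D_ij = arccos( Σ_I ξ_I^i ξ_I^j ),

the arccosine of the Bhattacharyya coefficient. The pipeline is:

1. **Estimate** each group's distribution non-parametrically under a
   question-independence (factorization) assumption: `p_I = Π_q f_q(a_q(I))`
   with `f_q` the plug-in per-question answer frequencies (optional
   pseudocount smoothing). The Bhattacharyya coefficient then factorizes as
   `Π_q Σ_a √(f_q¹ f_q²)`, so distances never require enumerating the
   `N_A^N_Q` strings.
2. **Embed** the K×K Fisher distance matrix with classical (Torgerson)
   MDS; a scree plot of the eigenvalue spectrum guides the choice of
   dimension, and a full-rank-MDS-then-PCA variant is available for data
   with high intrinsic dimension.
3. **Validate / probe**: a simulation framework places groups on a known
   one-parameter curve on the hypersphere and scores the recovered
   embedding against the exact geometry (Pearson correlation of distance
   matrices, Procrustes alignment, multipartite-information colouring);
   a question-ablation tool attributes an outlying group's separation to
   individual questions.

## Worked example

Simulate a ground-truth study (20 groups on the curve with `κ=1, m=3`,
8 ternary questions, 25 respondents per group), run the full pipeline on
the sampled responses, and compare the 2-D embedding with the exact
geometry:

```python
from qmanifold import CurveSpec, run_validation

spec = CurveSpec(n_questions=8, n_answers=3, kappa=1, m=3)
report = run_validation(spec, n_groups=20, n_per_group=25,
                        n_components=2, seed=0)
print(f"Pearson r (embedding vs exact Fisher geometry): {report.pearson_r:.3f}")
print(f"multipartite information across groups: "
      f"{min(report.group_mi):.3f} .. {max(report.group_mi):.3f} nats")
```

prints

```
Pearson r (embedding vs exact Fisher geometry): 0.915
multipartite information across groups: 0.000 .. 0.607 nats
```

`r = 0.915` says the 2-D map reproduces the true inter-group geometry
almost perfectly even with only 25 respondents per group; the
multipartite-information range shows the simulated groups span
near-independent to strongly correlated questionnaires, so the
factorization assumption is genuinely stressed.

The same is available from the shell:

```sh
qmanifold validate --nq 8 --na 3 --m 3 --groups 20 --n-per-group 25 --seed 0
qmanifold simulate --nq 3 --na 2 --kappa 1 --m 2 --groups 6 \
    --n-per-group 15 --seed 4 --out simdemo/
qmanifold embed my_responses.csv -g region --out results/
qmanifold ablate my_responses.csv -f outlier_group --out ranked.csv
```

`embed` expects a CSV with one respondent per row: one or more grouping
columns (several are crossed, e.g. ethnicity × smoking) followed by one
column per question; answers are opaque categorical codes. It writes the
labelled Fisher distance matrix, the embedding coordinates, the eigenvalue
spectrum with a scree elbow suggestion, and a run log with every parameter
needed to reproduce the output.

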