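# Methods

## Model

Respondent groups are modelled as points on the statistical manifold of
categorical response distributions. For a questionnaire with `N_Q`
questions and alphabets `A_q`, a response string `I` is one respondent's
ordered answer sequence and a group `k` is the distribution `p_I^k` over
the `N = Π_q |A_q|` strings. Square-root coordinates `ξ_I = √p_I` embed
every distribution on the positive quadrant of the unit `(N−1)`-sphere,
where the Fisher information metric coincides with the round-sphere
metric; the geodesic (Fisher) distance between two groups is therefore the
great-circle arc

    D_ij = arccos(Σ_I ξ_I^i ξ_I^j) ∈ [0, π/2],

the arccosine of the Bhattacharyya coefficient. Classical (Torgerson) MDS
of the K×K matrix `D` yields the group map. This treats the *geometry*
exactly — no assumption that the manifold is densely sampled or that
neighbouring distributions are close (both distributions enter through one
global inner product, not through chained local approximations).

### Estimation and the factorization assumption

Group distributions are estimated non-parametrically. Because `N` is
exponential in `N_Q`, the joint is estimated under question independence
within each group:

    p_I = Π_q f_q(a_q(I)),   f_q(a) = (count_q(a) + α) / (n + α|A_q|).

The Bhattacharyya coefficient then factorizes into a product of
per-question sums, so distance computation is `O(K² N_Q N_A)` and the
exponential string space is never materialised. The factorized and
full-enumeration paths are algebraically identical on factorized
distributions; the enumeration path is retained for ground truth and is
tested to agree to 1e-12.

The assumption is of course wrong for correlated questions — that is
quantified, not hidden: the multipartite information (total correlation)

    MI = Σ_I p_I ln( p_I / Π_q p_q(a_q(I)) )   [nats]

is zero iff the factorization is lossless, and the validation framework
tracks it per group. Empirically (see the validation tests) the embedding
geometry survives substantial MI, degrading gracefully.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0 | pseudocount per answer cell. 0 is the plug-in estimate; with 0, groups with disjoint support on any question sit at the maximal distance π/2. A small positive value softens that saturation. Units: respondents. |
| `n_components` | 2 | embedding dimension; `"auto"` takes the scree elbow. |
| `pca_components` | off | two-stage variant: full-rank MDS, then PCA projection — for data whose scree plot indicates intrinsic dimension well above 2 but a 2-D picture is wanted (the retained-variance fraction is reported). |
| `min_group_size` | 20 | advisory validation threshold; embedding accuracy rises steeply with group size up to roughly 20–25 respondents and then levels off, so smaller groups are flagged, never blocked. |
| `kappa`, `m` | 1, 1 | simulation curve: which spherical angle carries the `(π/2)sin²(mπt)` term and how many oscillations it makes; all other angles grow linearly as `(π/2)t`. Larger `m` = more non-linear group manifold. |
| `placement` | uniform | group positions `t_k` on the curve: uniformly spaced with both endpoints (`t_k = (k−1)/(K−1)`) or sorted uniform draws. |

## Conventions and numerical choices

- **String order.** Flat probability vectors index strings
  lexicographically by answer code with question 1 most significant
  (mixed-radix, leftmost digit highest). Spherical coordinate `ξ_j`
  corresponds to the j-th string in that order. Any fixed bijection would
  do; this one is reproducible and is versioned in the run log.
- **arccos clipping.** Products of per-question sums can exceed 1 by a few
  ulps; coefficients in `(1, 1+1e-9]` clip silently. Values below `−1e-12`
  or beyond that slack raise — they indicate a broken distribution, not
  roundoff.
- **Negative eigenvalues.** Fisher matrices are not exactly Euclidean, so
  the double-centered Gram matrix has negative eigenvalues. They are
  reported in the spectrum (they measure the non-Euclideanity) and never
  used for coordinates; a requested dimension exceeding the positive count
  is truncated with a warning. Raw stress is consequently non-monotone in
  dimension near full rank on such matrices: tiny trailing positive
  eigenvalues can overshoot. The dominant dimensions are unaffected.
- **Sign convention.** Each eigenvector (and PCA) column is flipped so its
  first nonzero coordinate is positive, making output files byte-stable.
- **Matrix correlation.** Pearson r between distance matrices uses the
  strictly upper triangle only — the zero diagonal would inflate r and the
  lower triangle is redundant.
- **Unseen answers** stay in the alphabet with frequency 0 so vector
  dimensions stay aligned across groups.
- **Procrustes.** Alignment allows translation, rotation, reflection and
  isotropic scaling; the disparity is the residual normalised by the
  target's centered sum of squares.
- **Ablation line fit.** The outlier-attribution tool measures the focal
  group's perpendicular distance from the *total-least-squares* line
  through the other groups' embedding points. Perpendicular (orthogonal)
  residuals are rotation-invariant, so the result does not depend on the
  arbitrary orientation of the MDS solution; an ordinary regression of one
  coordinate on the other would. If the non-focal groups collapse to one
  point after removing a question, the distance to that common point is
  used. When several sub-groups share a super-label, their centroid is
  used as the cluster's centre of mass.

## The simulation framework

The generator emulates grouped categorical responses whose joint
distributions lie on a known one-parameter curve on the hypersphere:
angles from the `(κ, m)` family above, coordinates via generalised
spherical coordinates, probabilities `p_I = ξ_I²`, and `n` i.i.d. strings
per group sampled from the exact joint. One seeded RNG stream drives a
study, with groups sampled in `t` order — so a study is fully reproducible
from `(spec, K, n, placement, seed)`, and adding groups changes all draws.

The defaults used throughout validation mirror the curve study design:
`κ=1, m=3`, 8 questions with 3 answers each (`N = 6561`), and two regimes
— 50 groups × 50 respondents (headline) and 20 groups × 25 respondents
(small-sample). Under these conditions the 2-D embedding correlates with
the exact geometry at median r ≈ 0.93 (headline) and clears r = 0.9 in
most replicates even in the small-sample regime.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: within-group question correlations (the
sampled joints are exactly the curve joints, which the factorized
estimator can represent in the large-n limit; real groups can have
structurally correlated questions), missing answers, ordinal answer
scales, unequal group sizes, and respondent-level heterogeneity within a
group. Real-data behaviour is probed instead through the ablation tool and
the advisory table validation.

A curve-family caveat: for `κ=1` and integer `m` the curve's two endpoints
coincide (`φ_1(0) = φ_1(1) = 0` puts both at the first basis vector), so
`t` is not injective there; validation protocols use the distance-matrix
correlation, which is unaffected.

## Known limitations

- The factorized estimator cannot represent within-group question
  correlations; strongly correlated blocks would need joint estimation
  over those blocks (out of scope here).
- With `α = 0`, zero-overlap questions saturate distances at π/2,
  flattening the geometry among very distinct groups.
- Group discovery is not addressed: the grouping variable is supplied by
  the analyst.
- Classical MDS is the only embedding offered; non-classical variants
  (SMACOF, t-SNE) are deliberately out of scope.

## Problem sizes in the test suite

The suite runs the headline regime (50×50, 10 replicates), the
small-sample regime (20×25, 10 replicates) and a sample-size sweep
(n ∈ {10, 25, 50, 100} at K=20, 10 replicates each); together they
complete in about a minute. The acceptance script re-runs the headline
regime only.
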