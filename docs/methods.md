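# Methods

## Segmentation model

A grayscale image `I` (gray levels `0..L−1`, `L = 256` by default) is
paired with its nonlocal-means image `g`. The filter replaces each pixel
with the similarity-weighted average of the gray values in its search
neighborhood, where similarity is the squared difference of *local patch
means* — `ω(p,q) = exp(−(μ(p)−μ(q))²/σ²)`, `μ` the m×m box mean. This is
deliberately not the classical patch-sum-of-squares NLM: the patch-mean
variant is the one the 2D-histogram model is defined on, and it is what
the brute-force oracle in the tests transcribes. Defaults: patch side
`m = 3`, decay `σ = 10` gray levels, search window 21×21 (a `window=None`
mode sums over the whole image for small oracle tests; it is quadratic in
pixel count). Borders use symmetric padding. The filtered image is rounded
back to integer gray levels so that the L×L joint histogram of
`(gray, filtered-gray)` pairs is well defined.

`k` thresholds cut the normalized joint histogram `P` into `k+1` square
blocks along the main diagonal (the standard diagonal approximation: a
single threshold vector indexes both axes, and off-diagonal mass is
ignored). The objective is the summed Shannon entropy of the
block-conditional distributions, with the conventions `0·ln 0 = 0` and
empty blocks contributing 0. Internally the entropy uses two summed-area
tables (of `P` and `−P ln P`), making each block O(1):
`H_block = S_plogp/P_m + ln P_m`. The tests check this against a literal
double-loop transcription to 1e−10 on random histograms.

Degenerate behavior worth knowing: if each class occupies a *single* gray
level (a noise-free piecewise-constant image), the block-entropy sum is
maximized by *merging* the spikes into one block (`ln 2 > 0 + 0`), so the
criterion will not separate them. The criterion presupposes that each
mode has spread over several gray levels — true of any real or noisy
image, and of the synthetic fixtures used here.

Continuous optimizer positions are decoded to thresholds by
round → clamp to `[1, L−2]` → sort → duplicate repair (push the later
duplicate up, cap at `L−2`, then pull earlier ones down). Pixels with
gray value in `(t_r, t_{r+1}]` get label `r`; the rendered segmentation
paints each region with its rounded mean gray, which is what the
PSNR/SSIM/FSIM scores compare against the original.

## Optimizer

Minimization convention throughout; the segmentation objective is the
negated entropy. Baseline WOA per iteration and individual: with
probability ½ the shrink/search branch — `A = 2a·r₁ − a` and `C = 2r₂`
drawn per dimension, dimensions with `|A| > 1` move relative to a random
member (`X_rand − A·|C·X_rand − X|`), the rest encircle the best
(`X_best − A·|C·X_best − X|`) — and with probability ½ the logarithmic
spiral `|X_best − X|·e^{bl}·cos 2πl + X`, `l ~ U[−1,1]`, `b = 1`. The
control scalar decays linearly `a = 2(1 − FEs/MaxFEs)` over the
*evaluation* budget, not iterations; every objective call counts exactly
one evaluation, and the budget is a hard cap (a final partial population
pass evaluates only as many members as remain).

The three strategy toggles:

- **COSI.** `X = cos(π(½ − p)·b)(ub − lb) + lb` with `p` a Latin
  hypercube sequence (one uniform sample per stratum per dimension) and
  `b ~ U[0,1]` per entry. As printed, the map is skewed: small `b` sends
  samples toward `ub` (the argument shrinks toward 0 and the cosine
  toward 1). This is implemented exactly as the formula states; the
  stratification invariant is asserted on `p`, not on the transformed
  positions.
- **GS.** Before the WOA phase, every member is overwritten by
  `X_best + 2C(X_rand1 − X_rand2)`, `C = 2b·e^{FEs/MaxFEs}`, rand1 ≠
  rand2 ≠ self. Overwrite (rather than greedy acceptance) is the default
  composition; a `gs_greedy` flag switches to per-member greedy
  acceptance with its own evaluation pass. Overwriting costs no extra
  evaluations and keeps population diversity; greedy acceptance is
  markedly more exploitative and noticeably worse on plateaued discrete
  objectives like decoded-threshold entropy.
- **ADN.** With probability `ρ` (default 1.0) per iteration, `2·dim`
  probes `X_best ± L_d·e_d` are evaluated and merged into the population
  elitistly (keep the N best of the union; stable sort, incumbents win
  ties — determinism and monotonicity follow). The step vector starts at
  `L₀ = 0.1·(ub − lb)`, is kept unchanged when the probe round improved
  the best (maintenance), shrinks by `s = 0.5` otherwise, and any
  component falling below `L_min = 10⁻⁴·(ub − lb)` is re-expanded to
  `L₀·r`, `r ~ U[0,1]` — so the probe scale never stays degenerate for
  two consecutive rounds. The maintenance state reflects the three
  named step behaviors (contract, expand, maintain); the `improved`
  flag is how the third is triggered.

Other numerical choices: boundary handling is projection (clamping);
non-finite objective values are recorded as `+∞` so they are never
adopted; all randomness flows through one seeded `numpy` generator, so a
(seed, config) pair reproduces traces bit-identically. The best-so-far
is elitist across the whole run, which makes the per-iteration trace
non-increasing by construction for every strategy combination.

The 8 ablation variants are the 2³ flag combinations, named by prefix
letters (C = COSI, G = GS, A = ADN): CAGWOA, AGWOA, CGWOA, CAWOA, GWOA,
AWOA, CWOA, WOA.

## Quality metrics

PSNR: `20·log₁₀(255/√MSE)`, `+∞` sentinel for identical images
(serialized as JSON `null`). SSIM: windowed default delegates to
scikit-image's reference implementation (11×11 Gaussian window σ=1.5,
`k₁ = 0.01`, `k₂ = 0.03`, dynamic range 255, population covariance); a
`global` mode evaluates the same formula once on whole-image moments and
is the closed-form oracle in tests. FSIM: gradient similarity (Scharr)
times phase-congruency similarity, weighted by the pointwise maximum
phase congruency; phase congruency is a simplified multi-scale log-Gabor
measure (4 scales, 4 orientations, `|Σ responses| / Σ |responses|` per
orientation, no noise compensation) — deterministic, symmetric, exactly 1
on identical inputs, in `[0, 1]`. A `gradient_only` fast mode drops the
phase-congruency term for cheap batch scoring. Constants `T₁ = 0.85`,
`T₂ = 160` on the 8-bit range.

## Experiment harness

Algorithms are callables `(objective, space, n, seed) → final best`;
repetition `r` uses seed `base_seed + r` for every algorithm so
comparisons are paired. Reductions: per-cell AVG and sample STD
(ddof = 1; STD 0 for a single rep); Friedman mean ranks computed on AVG
per problem with average-rank ties (rank sums per problem are
`A(A+1)/2`); two-sided Wilcoxon signed-rank at `α = 0.05` per problem
('+' reference significantly better, '−' worse, '=' otherwise; all-zero
difference vectors are ties; zeros dropped by default, Pratt handling
behind a flag; scipy uses the exact distribution at small rep counts).

Default conditions: population 30 and 30 repetitions for benchmark runs
(full-scale studies of this kind use a 300,000-evaluation budget; the
test and acceptance runs here use 30,000 at dim 10 so the whole suite
fits in minutes on one core — the comparisons are the same paired,
seeded procedure at reduced scale). Segmentation runs default to
population 20 and 100 iterations; the iteration count is converted to an
evaluation budget of `n + iters·(n + 2k)` so that ADN probes are
budgeted explicitly.

## Synthetic fixtures

`make_multimodal_image` produces piecewise-constant horizontal bands at
the mode means plus clipped Gaussian noise — by default three modes at
30/128/220 with σ = 8 on a 128×128 canvas, i.e. well-separated intensity
classes of equal area with mild overlap-free noise, emulating the
multi-peaked gray structure of chest X-rays. It returns the generating
label map so recovery can be scored exactly. What it does *not* emulate:
spatial texture, anatomy, vignetting, or correlated noise — so passing
the recovery tests shows the estimator chain is correct, not that the
method handles arbitrary clinical images. `reduce_gray_levels`
(`floor(v·L_t/L)`) shrinks the gray range to L=16 where exhaustive
enumeration of all threshold sets is tractable and can serve as the
optimality oracle. Toy histograms (single-cell, uniform-diagonal,
k-block with one-cell gaps) give closed-form entropy cases; note a
threshold anywhere in an empty gap is optimal, so block-boundary
assertions accept the gap range.

## Known limitations

- The COSI map's skew toward `ub` (above) means initial coverage of low
  coordinate values relies on the search phases, not initialization.
- The diagonal 2D-Kapur objective ignores off-diagonal histogram mass;
  heavy edge content (gray ≠ filtered gray) is invisible to it.
- FSIM here is a self-consistent simplified construction, suitable for
  relative comparison within this package rather than replicating any
  specific published FSIM number.
- The full-image NLM mode is O(P²) in pixel count and intended only for
  small oracle images.
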