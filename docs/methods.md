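# Methods

## Setting and privacy model

All statistics are computed on a single-SNP case-control contingency
table for a cohort of N individuals, exactly N/2 per disease-status
column. The 3×2 genotype table is parameterized by (a, b, m, n, N) —
first-column genotype-0/1 counts and the two row margins — and the 2×2
allele table by (a, m, N); the remaining cells are derived. All row
margins must be positive, which is what a GWAS that removed SNPs with
MAF < 0.05 guarantees. Tables with N < 100 are accepted with a
warning: the closed-form sensitivities are derived for N ≥ 100, and
the enumeration oracle is the tool of record below that.

Two cohorts are *neighbors* when they differ in one individual's
genotype, with both group sizes fixed. On the genotype table this is
one of 12 moves (6 genotype transitions × 2 columns); on the allele
table a one-step genotype change moves one allele and the 0↔2 change
moves two, so allele deltas are ±1 or ±2, in the first column jointly
on (a, m) and in the second on m alone. Changing an individual's
*disease status* instead would unbalance the columns and is not part
of this neighbor model.

The release mechanism is the Laplace mechanism: a statistic f with
sensitivity Δf (the maximum |f(D) − f(D′)| over neighbors) is
published as f + Laplace(0, Δf/ε), which is ε-differentially private.
ε is a per-SNP budget; composition across SNPs (and across correlated
SNPs in LD) is deliberately out of scope, and the batch API logs a
warning saying so.

## Statistics and numerics

- **χ² tests.** Pearson χ² on the 3×2 table (2 df) and the 2×2 table
  (1 df). With balanced columns the expected count of every cell is
  half its row margin, giving the reduced forms used throughout
  (2×2: χ² = 2N(2a−m)²/(m(2N−m))).
- **Trend test (CATT).** T = N(2m+n−2(2a+b))² / (4Nm+Nn−(2m+n)²),
  the score test for a linear trend in case proportion across dosage
  scores (0, 1, 2). Its reference distribution is taken as χ² with
  **2 df by default** (`catt_df=2`), the convention this package
  standardizes on for the 3×2 table; the common textbook choice of
  1 df is available via the flag. The choice affects P-values only,
  not the statistic or its sensitivity.
- **Fisher's exact test.** The released "P-value" is the *point*
  probability of the observed table under fixed margins
  (2×2: C(N,a)·C(N,m−a)/C(2N,m); 3×2: the multivariate analogue),
  **not** the conventional tail sum. The point probability is the
  quantity with a closed-form sensitivity; docstrings flag the
  discrepancy with standard Fisher tests.
- **Log-space P-values.** −log10 P is computed without ever forming P:
  for 2 df it is exactly x/2·log10(e); for 1 df via the log of the
  normal tail (p = 2Φ(−√x), using `log_ndtr`); for the exact tests
  via log-gamma. Values stay finite and accurate for statistics up to
  at least 10⁴ and cohorts beyond 10⁶ (verified against a 50-digit
  reference in the tests). P = 0 is therefore impossible by
  construction on the −log10 scale.

## Sensitivities

Closed forms for each (test, form) pair are tabulated in
`dpgwas/sensitivity.py`. Notable cases:

- The −log10 P sensitivities of the 2-df tests are exactly
  log10(e)/2 times their statistic sensitivities (the map is linear);
  this identity is asserted in the tests.
- The 2×2 χ² **P-value** sensitivity is the 1-df χ² CDF at N/(N−2),
  evaluated by quadrature after the substitution x = t² (the raw
  integrand has an integrable singularity at 0); tolerance 1e−10.
- The 2×2 χ² **−log10 P** form has no exact closed form; the
  mechanism is calibrated with the constant upper bound 2.33 (the
  computed bound, −log10 of the 1-df survival-function ratio at
  statistics 0 and 8, is ≈ 2.3299 and is exposed read-only). A looser
  scale never weakens the privacy guarantee.
- Unsupported pairs (raw P for the 2-df tests, any "statistic" for
  the exact tests) raise rather than fall back: for those the noise
  would exceed any useful value and no bound is derived.

**Brute-force oracle.** `brute_force_sensitivity` enumerates the full
count lattice ((a, m) up to N = 200 for 2×2; (a, b, m, n) up to
N = 100, ~3×10⁶ valid states, for 3×2) as a dense NumPy array with
NaN outside the valid domain, so each move class reduces to a shifted
absolute difference. It reports the maximum separately over (i) the
restricted move class used in the closed-form derivations (double
allele flip (a−2, m−2); genotype move (a−1, b, m−1, n)) and (ii) all
single-individual moves. At N = 100 the restricted class attains every
closed form to 1e−9 and no move exceeds it; maximizers are reported
up to column symmetry (the statistics are invariant under swapping the
status columns, so mirrored argmaxes are equivalent). The full CATT
scan at N = 100 runs in well under a minute on one CPU.

## Mechanism details

Noise is generated by the inverse-CDF transform
−scale·sign(u−½)·ln(1−2|u−½|) of uniforms from a seeded
`numpy.random.default_rng` stream, giving bit-reproducible releases.
Batch releases derive a per-record stream from SHA-256 of
(seed, record id) — noise follows the SNP, not its file position, so
permuting the input permutes the output.

Clamping (P into [0, 1], −log10 P to ≥ 0) is deterministic
post-processing, hence privacy-preserving, and can only shrink the
error; it is on by default for the bounded forms and off for raw
statistics. ε is accepted anywhere in (0, ∞) but values outside
[0.1, 10] — the range commonly studied for DP releases — are logged.

`empirical_dp_check` audits the ε-bound at a worst-case neighbor pair:
10⁶ draws per side, 50 shared histogram bins, and a per-bin slack of
z = 4 standard errors on add-one-smoothed counts (chosen so that with
~50 simultaneous bin comparisons the false-alarm probability is well
below 1%). The check provably must fail when the noise is undersized
by 2×, and the tests confirm it does.

## Synthetic data

`simulate_tables` draws, per SNP, a MAF uniform in [0.05, 0.5],
control genotypes from Hardy–Weinberg proportions, and case genotypes
from the same proportions reweighted by relative_risk^dosage
(multiplicative risk; 1.0 = null). Counts are multinomial conditioned
on exactly N/2 per group, matching the balanced-margins assumption
rather than binomial sampling of totals. Zero-margin draws are
rejected and redrawn (cap 1000, then a hard error). What this
emulates: marginal per-SNP sampling noise under HWE. What it does
not: LD between SNPs, population stratification, genotyping error —
so calibration results here say nothing about confounding in real
cohorts.

`simulate_statistic_population` provides the threshold-sweep
populations: raw 1-/2-df χ² draws, the same draws pushed through the
matching survival map onto the −log10 P scale, and an alternative
half-normal −log10 P generator whose scale σ = 7.3/Φ⁻¹(1−2.5×10⁻⁸)
≈ 1.37 puts exactly the nominal 5×10⁻⁸ mass above the genome-wide
threshold 7.3. Which of the two −log10 P generators is "right" is
genuinely open; both are exposed and neither is asserted as canonical.

## Utility experiments

**KL divergence.** For each true value v on a grid (χ² statistics 10,
20, …, 100; −log10 P 0, 2, …, 20) and each ε, `reps` (default 10⁴)
private releases of v are histogrammed against `reps` unperturbed
copies, with add-one smoothing. One set of 100 equal-width bins
spanning the pooled range of *all* cells is shared by the whole grid:
a fixed absolute bin width is what makes the divergence fall as ε
grows — noise-adaptive per-cell bins would rescale away exactly the
effect being measured. Under this estimator KL is monotone decreasing
in ε across the studied range. One consequence of clamping worth
noting: at v = 0 the clamp concentrates mass into the bin containing
the original value, so this estimator yields *smaller* KL at v = 0
than at large v.

**Threshold sweeps.** A population of statistics is drawn from its
reference distribution, ground truth is `value ≥ original threshold`,
noise is added once per datum (reused across all candidate
thresholds, as a data custodian would publish one noisy value per
SNP), and precision/recall/f-measure are computed per threshold via
sorted-array bisection. Default population size is 10⁶. At that size
the genome-wide cutoffs (29.7 / 33.6) leave essentially zero true
positives, so experiments scale the *threshold* to preserve the tail
geometry instead: the acceptance checks use the cutoff with tail mass
5×10⁻⁵, giving the same expected ~50 true positives as 5×10⁻⁸ does
at population 10⁹. Behavior is assessed qualitatively — f-optimal
threshold returns to the original cutoff as ε → ∞, sits above it
under heavy noise, recall monotone in the threshold — rather than by
matching any particular printed f-measure, which would require the
10⁹-scale populations.

## Known limitations

- Balanced designs only (N/2 cases, N/2 controls); unequal groups
  change the sensitivities and are not supported.
- Per-SNP ε with no composition or LD-aware accounting.
- Fisher releases use the point probability, not the tail sum; a
  consumer expecting a conventional Fisher P-value must not compare
  thresholds directly.
- The oracle certifies N ≤ 100 (3×2) / N ≤ 200 (2×2) exhaustively;
  for larger N the closed forms are trusted as derived, with their
  exactness checked at the certification point and their limits at
  N = 10⁹ checked algebraically.
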