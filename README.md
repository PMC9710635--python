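# dpgwas

Differentially private release of case-control association statistics
for GWAS summary data.

## The problem

Per-SNP test statistics and P-values from a genome-wide association
study leak information: with enough released statistics, membership of
a single individual in the case group can be inferred. `dpgwas`
releases the statistics of the three standard contingency-table tests —
the Pearson χ² test (3×2 genotype and 2×2 allele tables), Fisher's
exact test, and the Cochran–Armitage trend test — under
ε-differential privacy, for balanced cohorts of N/2 cases and N/2
controls with all table margins positive (the post-QC regime, MAF ≥
0.05).

A statistic f with sensitivity Δf = max |f(D) − f(D′)| over cohorts
D, D′ differing in one individual's genotype is released as
f(D) + Laplace(0, Δf/ε). The package supplies closed-form Δf for every
supported (test, released-form) pair, e.g.

| test | statistic | −log10 P |
|---|---|---|
| χ² 3×2 (genotype) | 4N/(N+2) | log₁₀(e)·2N/(N+2) → 0.87 |
| χ² 2×2 (allele) | 8N/(N+2) | < 2.33 (constant bound) |
| Fisher 2×2 | — | log₁₀((N+1)(N+2)/2) |
| Fisher 3×2 | — | log₁₀(N/2+1) |
| trend test (CATT) | 16N(N²+6N+4)/((N+18)(N²+8N−4)) | log₁₀(e)/2 × that |

(Fisher P-values here are the *point* probability of the observed
table; raw P-values are additionally supported for the 2×2 χ² and
Fisher tests.) Releasing −log10 P rather than P is what makes
genome-wide-significant values (P ≈ 5×10⁻⁸, −log10 P ≈ 7.3)
survive the noise: the −log10 sensitivities are O(1) for the χ² and
trend tests.

Every closed form can be *certified* by `brute_force_sensitivity`, an
exhaustive oracle that enumerates all valid tables at a given N and
all single-individual moves, and the mechanism's ε-bound can be
audited empirically (`empirical_dp_check`). A utility suite measures
what the noise costs: KL divergence between original and private
statistic distributions, and precision/recall/f-measure sweeps over
significance thresholds.

## Worked example

Simulate a small cohort, inspect the sensitivity, release private
−log10 P-values:

```sh
$ dpgwas simulate -N 2000 --n-snps 4 --seed 7 --out counts.tsv
$ dpgwas sensitivity --test chi2_3x2 --form neg_log10_p -N 2000
chi2_3x2  neg_log10_p  2000  0.867721242564  3x2 chi-square log10 P closed form
$ dpgwas release --test chi2_3x2 --form neg_log10_p --epsilon 5 \
      --seed 11 --in counts.tsv --out rel.tsv
INFO dpgwas: test=chi2_3x2 form=neg_log10_p N=2000 epsilon=5 sensitivity=0.867721 scale=0.173544
WARNING dpgwas.mechanism: per-SNP epsilon=5: releasing 4 SNPs does NOT compose to a total budget of 5
$ cat rel.tsv
snp_id  test      form         n_total  epsilon  scale                released             clamped  seed
snp1    chi2_3x2  neg_log10_p  2000     5        0.17354424851278794  0.2317619409302269   0        11
snp2    chi2_3x2  neg_log10_p  2000     5        0.17354424851278794  0.36343805627413878  0        11
snp3    chi2_3x2  neg_log10_p  2000     5        0.17354424851278794  0.25395798071746728  0        11
snp4    chi2_3x2  neg_log10_p  2000     5        0.17354424851278794  0.33923076672060493  0        11
```

Each released value is the SNP's true −log10 P (here all null SNPs,
so near 0) plus seeded Laplace noise at scale Δf/ε = 0.8677/5; noisy
values below 0 would be clamped to 0 (`clamped` column). The warning
is deliberate: ε is a **per-SNP** budget and composes across SNPs.

The same from Python:

```python
from dpgwas import build_genotype_table, run_test, release_value

gt = build_genotype_table(case_counts=(448, 428, 124),
                          control_counts=(459, 430, 111))
res = run_test(gt, "chi2_3x2")          # statistic, p, neg_log10_p
rel = release_value(res.neg_log10_p, "chi2_3x2", "neg_log10_p",
                    N=gt.N, epsilon=5, seed=11)
```

Certify a closed form by exhaustive search:

```sh
$ dpgwas oracle --test catt --form statistic -N 100
test  form       N    closed_form    oracle_proof_moves  oracle_all_moves  ...
catt  statistic  100  13.3181781074  13.3181781074       13.3181781074
```

The maximizing neighbor pair is (a,b,m,n) = (1,0,2,49) → (0,0,1,49):
the sensitivity is attained at an extreme low-MAF corner of the table
domain, which is why the MAF ≥ 0.05 / positive-margin assumption
matters.

## Layout

- `dpgwas.tables` — table types, validation, neighbor enumeration
- `dpgwas.teststats` — the five tests, log-space P-value numerics
- `dpgwas.sensitivity` — closed forms + brute-force oracle
- `dpgwas.mechanism` — seeded Laplace release, clamping, DP audit
- `dpgwas.evalsuite` — KL divergence and threshold-sweep experiments
- `dpgwas.simdata` — synthetic cohorts and statistic populations
- `dpgwas.io` / `dpgwas.cli` — TSV schemas and the `dpgwas` command

See `docs/methods.md` for the model, parameter choices and known
limitations.
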