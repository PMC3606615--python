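# hwesurvey

Design-based tests of Hardy–Weinberg equilibrium (HWE) for parent–parent–child
**trio** genotype data collected in national genetic household surveys —
samples with stratified multistage cluster designs, differential sampling
weights, and two levels of correlation: geographic clustering of families
within primary sampling units (PSUs), and Mendelian inheritance within
families.

It is written for statistical geneticists and survey methodologists who need
an HWE check that remains valid (and reasonably powerful) when the data are
*not* a simple random sample of unrelated individuals.

## The tests

For a biallelic autosomal locus with allele-A frequency $p_A$, departure from
HWE is parameterized by the fixation index $r$ (the correlation between the
two alleles within an individual):

$$P(AA) = (1-r)p_A^2 + r\,p_A,\qquad P(Aa) = 2(1-r)p_A p_a,\qquad
P(aa) = (1-r)p_a^2 + r\,p_a .$$

Two families of design-based tests of $H_0\!: r = 0$ are implemented:

**Corrected chi-square (CCS) family.** A Mendelian trio falls into one of 10
familial types (unordered parental pair × child genotype); under HWE the type
probabilities are $\pi(p_A) = (p_A^4,\, 2p_A^3p_a,\, \dots,\, p_a^4)$. With
weighted type counts $J_w$ (total $T_w$) and
$\hat\pi = \pi(\hat p_{Aw})$, the weighted Pearson statistic is

$$\chi^2_{A,W} = \sum_{l=1}^{10} \frac{(J_{lw} - T_w\hat\pi_l)^2}{T_w\hat\pi_l}.$$

Under complex sampling this is not chi-square distributed; Rao–Scott
corrections rescale it by the eigenvalues $\hat\lambda_1,\dots,\hat\lambda_8$
(generalized design effects) of $\hat\Sigma M$, where $\hat\Sigma$ is a
Taylor-linearization estimate of the design covariance of the residual
vector: the first-order correction $\chi^2_{A,W}/\bar\lambda$ (vs
$\chi^2_8$), the second-order correction (additionally divided by $1+\hat
b^2$, the squared CV of the eigenvalues, with Satterthwaite df), and an F
version referred to $F\!\left(8/(1+\hat b^2),\, U-H\right)$ for $U$ PSUs in
$H$ strata.

**Quasi-score (QS) test.** Each individual contributes indicators
$y=(1\{AA\}, 1\{Aa\})$ with mean $\mu(p, r)$; quasi-generalized estimating
equations sum $D^\top W^{1/2}\mathrm{Var}(y)^{-1}W^{1/2}(y-\mu)$ over
families, where the 6×6 trio covariance is built from kinship: spouses
independent, each parent–child pair sharing one allele identical by descent.
With $\tilde p$ solving the null $p$-equation, the test refers
$QS = S_r(\tilde p)^2/\hat V_L$ to $F(1, U-H)$, with $\hat V_L$ a
design-based (stratified between-PSU) variance of the effective $r$-score.

The uncorrected $\chi^2_{A,W}$ is included as the cautionary benchmark: its
scale grows with the mean weight and it ignores clustering entirely.

## Worked example

```bash
python examples/test_one_sample.py
```

simulates a finite population of 100,000 trio families at $p_A=0.3$ with a
mild homozygote excess ($r=0.05$), samples 60 PSUs of 40 families with
noninformative {1,3,5} weights, and prints:

```
test           statistic            df   p-value
chisq_naive       58.163          8.00    0.0000
chisq_rs1         15.137          8.00    0.0565
chisq_rs2         13.505          7.14    0.0649
chisq_rs2_F        1.892      7.14, 59    0.0857
qs                 8.056      1.00, 59    0.0062

weighted allele frequency p_hat = 0.3082, mean design effect lambda_bar = 3.84,
null-fitted p_tilde = 0.3082
```

The uncorrected statistic's tiny p-value is mostly weighting artifact (its
mean design effect here is $\bar\lambda = 3.84$); after correction the
chi-square family is borderline, while the quasi-score test — which uses the
trio covariance structure rather than a 10-cell goodness of fit — clearly
detects the homozygote excess.

Other examples: `examples/power_study.py` (Monte-Carlo size/power table),
`examples/family_table_io.py` (the tab-delimited family-table format),
`examples/household_survey_demo.py` (synthetic 307-family household-survey
frame with Beta/binomial genotypes).

A CLI mirrors these workflows: `hwesurvey simulate`, `hwesurvey test`,
`hwesurvey power-study`, `hwesurvey hhanes-example` (see `--help`).

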