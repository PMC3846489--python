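# hdimpute

Tools for studying the accuracy of SNP-genotype imputation from a
medium-density panel up to a high-density (HD) panel in livestock
populations — the design question behind two-tier genotyping strategies,
where a reference population is genotyped on the HD chip and everyone else
is imputed up from the cheaper chip.

The package simulates pedigreed breed populations with realistic linkage
disequilibrium (coalescent founders, Mendelian gene drop), applies routine
array quality control, imputes masked genotypes with a Li–Stephens
haplotype-copying HMM, and quantifies accuracy and its drivers:

* **allelic imputation error rate** — falsely imputed alleles / imputed
  alleles, overall, per animal and per SNP, with het↔hom counting one
  wrong allele and opposite homozygotes two;
* **LD decay** r² = (p_AB − p_A p_B)² / (p_A q_A p_B q_B) from phased
  haplotypes, summarized at 70 kb (the informative-marker spacing of a
  medium-density chip);
* **pedigree relationships** (Wright's numerator relationship, tabular
  method) and the mean reference/validation relationship R_T/V;
* **effective number of ancestors** N_a = 1/Σ c_k² from greedy
  probability-of-gene-origin marginal contributions c_k;
* a breed-level **OLS factor regression** of error rate (%) on reference
  size, R_T/V, LD at 70 kb and N_a, with sequential variance shares;
* per-SNP **mismapped-marker detection**: markers whose imputation error
  exceeds a breed's mean + 3 SD in several breeds at once.

## Worked example

Simulate a dairy-like breed (~400 HD-genotyped animals, LD at 70 kb ≈
0.2), split off the youngest 20%, mask their HD-only markers and re-impute
them from the older animals:

```python
from hdimpute import SimConfig, simulate_dataset
from hdimpute.evaluate import evaluate_breed

data = simulate_dataset(SimConfig(seed=1))
report, info = evaluate_breed(data)
print(f"reference animals : {len(info['training_ids'])}")
print(f"validation animals: {len(info['validation_ids'])}")
print(f"allelic error rate: {report.overall_error:.5f}")
```

prints

```
reference animals : 323
validation animals: 80
allelic error rate: 0.00162
```

i.e. 99.84% of the 1.52 million masked alleles are imputed correctly —
the level expected for a breed with more than 300 HD reference animals.
Dropping the reference to a few dozen animals, or simulating a breed whose
validation animals are weakly related to the reference, raises the error
by an order of magnitude; `hdimpute.regression.fit_factors` quantifies
these effects across breeds (on the packaged 15-breed table, each 100
reference animals are worth about −0.27% error and each +0.01 of R_T/V
about −0.12%).

A `hdimpute` command-line tool exposes the same stages
(`simulate`, `qc`, `impute`, `evaluate`, `ld`, `relate`, `ancestors`,
`regress`, `detect-bad-snps`); see `hdimpute --help`.

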