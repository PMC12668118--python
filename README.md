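# embgwas

Image-embedding phenotypes for genetic association, exercisable end to end
on seeded synthetic cohorts. The package implements:

- **`synthcohort`** — seeded cohort generator: genotypes with first-order
  Markov LD, age-structured per-image features (with paired left/right
  observations), planted per-variant effects, and logistic disease labels.
- **`contrastive`** — ranked contrastive alignment of feature vectors to a
  continuous label (age): the rank-contrast loss with analytic gradients, a
  small numpy MLP encoder trained with AdamW, group-aware 5-fold
  72/8/20 splits, and ridge linear/logistic probes.
- **`embedding`** — eye averaging, PCA reduction (sign-fixed, reusable
  projection), rank-based inverse normal transformation, covariate design
  construction, and residualization.
- **`multitrait` association (`assoc`)** — multivariate score test of each
  variant against the K-dimensional embedding phenotype (chi-squared, K df),
  a one-step refined likelihood-ratio variant, a univariate per-dimension
  baseline combined with the aggregated Cauchy test, gene-burden testing,
  and permutation-null calibration (lambda_GC, KS uniformity, QQ data).
- **`loci`** — greedy LD clumping of summary statistics into independent
  loci (r² and window thresholds, both window conventions).
- **`axes`** — ridge-BLUP mixed model over embedding dimensions (REML via a
  1-d variance-ratio profile), closed-form leave-one-out random-effect
  scores, extreme-quantile mean embeddings, and linear interpolation
  between them.
- **`io` / `config` / `pipeline` / `cli`** — VCF and dosage-TSV readers and
  writers, schema-checked TSV tables, strict YAML config, and a `embgwas`
  command-line interface tying the stages together.

The encoder is a two-layer perceptron with hand-rolled backpropagation
(verified against finite differences); no deep-learning framework is
required.

## CLI

```bash
embgwas simulate --config cohort.yaml --out data/ --seed 1
embgwas train --features data/features.tsv --labels data/labels.tsv --out model/
embgwas probe --embeddings E.tsv --labels labels.tsv --target age
embgwas gwas --genotypes data/genotypes.vcf --embeddings E.tsv \
    --covariates C.tsv --mode score --maf-min 0.01 --out sumstats.tsv
embgwas gwas-univariate ... ; embgwas permute ... ; embgwas burden ...
embgwas clump --sumstats sumstats.tsv --genotypes data/genotypes.vcf \
    --p 5e-8 --r2 0.1 --window-mb 5 --out loci.tsv
embgwas axis --trait T.tsv --embeddings E.tsv --covariates C.tsv \
    --q 0.05 --alphas 0,0.25,0.5,0.75,1 --out axis.tsv
embgwas pipeline --config pipeline.yaml
```

A pipeline YAML needs at least a `seed`; see `embgwas.config.PipelineConfig`
for all keys (unknown keys are rejected).

## Notes

- Full-scale optimizer settings for large pretrained image encoders
  (learning rate 5e-6, weight decay 1e-5, batch 64) are recorded in
  `contrastive.FULL_SCALE_DEFAULTS`; the desk-scale `TrainConfig` defaults
  differ and are documented on the class.
- Desk-scale trait axes use a tail quantile of `q = 0.05` (cohorts of a few
  thousand); the full-scale convention is `q = 0.001`.
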