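# rgstab

Reference-gene (RG) selection and validation for real-time qPCR
normalisation: screen RNA-seq data for candidate RGs, model qPCR Cq data
with amplification-efficiency correction, score expression stability with
four independent estimators — geNorm, NormFinder, BestKeeper and the
comparative ΔCt method — and merge their rankings into a comprehensive
recommendation by the geometric mean of ranks.

## What's inside

| module               | purpose |
|----------------------|---------|
| `rgstab.qpcr`        | long-format Cq tables, technical-replicate averaging, efficiency correction `CqE = Cq·log(E)/log(2)`, relative quantities, boxplot summaries |
| `rgstab.screen`      | RNA-seq candidate screen: log2FC / FDR stability filter, coverage filter, per-gene ANOVA and Student's t-test across experimental groups |
| `rgstab.stability`   | the four stability estimators (lower value = more stable) |
| `rgstab.ranking`     | rank assignment, geometric-mean meta-ranking, scale-based method subsets |
| `rgstab.simulate`    | seeded generators for Cq tables (Gaussian on the cycle scale) and negative-binomial count matrices with ground-truth DE tables |
| `rgstab.workflow`    | glue running Cq table → estimators → comprehensive ranking |
| `rgstab.cli`         | `rgstab simulate / screen / stability / rank` |
| `rgstab.fixtures`    | bundled plain-text fixtures, including published within-method rank orders for three lettuce experiments |

Scale policy follows the study design: geNorm and NormFinder consume
efficiency-corrected cycles (geNorm as base-2 relative quantities);
BestKeeper and ΔCt consume mean raw Cq. All SDs use the n−1 denominator.

## CLI quick start

```bash
# synthetic six-gene Cq table, three irrigation groups
rgstab simulate --kind cq --seed 1 --out sim/

# stability values + ranks, one CSV per method
rgstab stability --cq sim/cq_table.csv --out stab/

# comprehensive ranking (plus CqE/Cq subset rankings)
rgstab rank --in stab/ --out ranked/

# RNA-seq candidate screen
rgstab simulate --kind counts --seed 1 --out rna/
rgstab screen --de exp1=rna/de_truth.csv \
              --counts exp1=rna/counts.tsv:rna/design.tsv \
              --out screen.csv
```

Options can also come from a YAML config (`--config`); CLI flags take
precedence. Exit codes: 0 success, 1 usage/config error, 2 data error.

## Notes on conventions

- Quartiles use linear interpolation; outliers use the Tukey 1.5×IQR rule
  and whiskers span the non-outliers (never retreating inside the box).
- geNorm ties on the worst M are broken by removing the lexicographically
  last gene; meta-ranking ties fall back to arithmetic mean rank, then
  gene name.
- Count tests run on counts-per-million by default (`--raw-counts` to
  disable); the t-test is the classic equal-variance form.
- There is no default amplification efficiency: pass `E = 2` explicitly to
  reproduce an uncorrected pipeline.
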