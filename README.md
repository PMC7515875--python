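# mei — Matched change characterization for Exons and Introns

Bulk RNA-Seq differential analysis conventionally tests exon counts for a
mean shift between two groups. Yet 20–40% of mapped reads fall in introns,
and a gene can change between conditions in ways a mean-shift test never
sees: its expression **variability** can change, or the coupling between
its exonic (mature) and intronic (nascent) signal can appear or break.
`mei` implements a coordinated exon/intron analysis for two-group studies
(control vs case) that scores every gene on six measures and expands the
differential gene list accordingly. It is written for bioinformaticians
analysing archived or fresh count data, from SAM alignments or pre-made
count matrices.

## The method

For each gene `g`, with calibrated exon counts `E` and intron counts `I`
across control (n₁) and case (n₂) samples:

| Symbol | Measure | Test |
|---|---|---|
| `E_p`, `I_p` | exon / intron expression change | negative binomial likelihood-ratio test (variance µ + αµ², common dispersion α by Cox–Reid adjusted profile likelihood, χ²₁) |
| `E_m` | exon mean-fold change, case/control | calibrated means with 0.5 pseudocount |
| `G_e`, `G_i` | exon / intron variability change | case/control ratio of unbiased Gini coefficients, G = Σᵢⱼ\|xᵢ−xⱼ\| / (2n(n−1)x̄) |
| `C_d` | exon:intron correlation change | Fisher z: Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) |

Selection criteria (defaults):

* **standard**: `E_p < 0.001` and ≥ twofold `E_m`;
* **MEI (expanded)**: `E_p < 0.001` and at least one of — twofold `E_m`,
  `I_p < 0.001`, `C_d < 0.005`, twofold change (either direction) in
  `G_e` or `G_i`.

The standard hit set is always a subset of the MEI set. Upstream, counts
are made *singular* (reads with MAPQ ≥ 40 mapping to exactly one gene;
genes dropped when low-quality alternatives exceed 1% of their total) and
calibrated per sample by ERCC spike-in regression or median-of-ratios.
A co-expression module clusters per-gene profiles (log₂, z-scored,
min-rescaled counts or exon:intron ratios) by K-means under correlation
distance with an information-criterion choice of k, and compares
partitions with the adjusted Rand index.

## Worked example

Simulate a 12-control / 46-case cohort with planted effects and analyse it:

```bash
$ printf 'n_genes: 500\n' > sim.yaml
$ mei simulate --config sim.yaml --seed 7 --out sim/
cohort with 500 genes -> sim
$ mei run --exon sim/exon.tsv --intron sim/intron.tsv --samples sim/sheet.tsv \
      --ercc sim/ercc_mix.tsv --spikes sim/spikes.tsv --no-cluster --out out/
25 standard hits, 25 MEI hits over 500 genes -> out
```

`out/mei_report.tsv` lists every gene with its six measures and flags,
sorted by number of satisfied criteria then by `E_p`; the leading rows of
this run were the planted fourfold mean-shift genes:

```
gene_id          E_p      E_m          I_p      C_d      G_e      G_i   Ep   Em   Ip    Cd    Ge    Gi
 G00077 6.621997e-89 3.910284 1.764561e-79 0.676417 0.754019 0.750755 True True True False False False
 G00239 8.337209e-81 3.978161 6.208467e-76 0.374738 0.883218 0.796601 True True True False False False
```

`E_p`/`I_p` are the NB test p-values (here vanishingly small: a real
fourfold shift at these depths), `E_m ≈ 4` is the recovered fold, and the
Gini/correlation columns stay unflagged because these genes change in mean
only. `out/run_log.json` records all thresholds plus the Benjamini–Hochberg
diagnostic (`bh_threshold_at_fdr_target`: the largest p-value cutoff that an
FDR of 0.1 would admit on both the exon and intron p-vectors — read it beside
the configured `ep_alpha`). Genes with secondary evidence but a failing
`E_p` gate go to a watch list (52 here, mostly planted variability and
correlation effects), not into the hit counts.

The same analysis is available as a library:

```python
import mei
cfg    = mei.default_cohort_config(seed=7, n_genes=500)
cohort = mei.simulate_counts(cfg)
factors = mei.ercc_calibrate(cohort.spikes, cfg.ercc_mix)
result  = mei.run_mei(mei.apply_factors(cohort.counts, factors), cohort.sheet)
print(result.report.table.head())
```

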