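# guidemeth

Genome-wide characterisation of on-target and off-target CpG methylation
deposited by RNA-guided dCas9 methyltransferases (dCas9–DNMT3A/3B catalytic
domain fusions), from per-CpG whole-genome bisulfite sequencing counts.

Targeted epigenome editing promises locus-specific DNA methylation, but an
overexpressed dCas9 methyltransferase also methylates elsewhere. `guidemeth`
implements the full analysis that separates the two: per-CpG methylation
quantification with a depth filter and lambda spike-in conversion control,
differentially methylated region (DMR) calling, a dose/gRNA monotonicity
filter that removes stochastic DMRs, genomic-feature / DNase-hypersensitive
site (DHS) / gRNA-seed-density enrichment, and DMR–ChIP-peak overlap.
Because the underlying experiment (nine transfection groups, deep human
WGBS) is not reproducible at desk scale, the package includes a first-class
synthetic-data generator that emulates the design with known injected
effects, giving every stage a ground-truthed test surface.

## Core model

For CpG site *i* in sample *s*, the methylation level is `M/N` (methylated
over total reads), used only when `N >= 4`. DMRs between conditions A and B
are called from smoothed levels (depth-weighted ±50 bp window) with a Wald
statistic per CpG,

```
z = (p1s − p2s) / sqrt( p̄(1−p̄)(1/n1 + 1/n2) + φ0 )
```

and grouped under the thresholds `delta >= 0.1`, `P <= 0.01`, `>= 3 CpGs`,
`length >= 10 bp`. A called DMR survives the stochastic-DMR filter only if
its group mean methylation respects the ordered dose/gRNA chains, e.g. for
uPA hypermethylated DMRs

```
level(g9 pUC19) ≤ level(g5 3A only) ≤ level(g7 3A+uPA 50ng) ≤ level(g1 3A+uPA 500ng)
level(g2 3B+uPA) ≤ level(g1),   level(g6 3B only) ≤ level(g2)
```

(mirrored for hypomethylated DMRs). Surviving DMRs are characterised
against matched random background windows (same number, same length
distribution) with Fisher exact tests, DHS metaplots with Wilcoxon
matched-pairs signed-rank tests, and 5nt-seed–NGG density scans on both
strands.

## Worked example

```python
from guidemeth.simulate import simulate_study
from guidemeth.dmr import cpg_test, call_dmrs
from guidemeth.chains import filter_dmrs
from guidemeth.design import UPA_FILTER
from guidemeth.methylation import conversion_rate

study = simulate_study(seed=1)                      # 5 Mb, 9 groups
print(f"conversion {conversion_rate(study.lambda_table):.2f}%")
res = cpg_test(study.table, ["g1_r1"], ["g9_r1"])   # 3A+uPA vs pUC19
dmrs = call_dmrs(res)
out = filter_dmrs(dmrs, study.table, study.design, UPA_FILTER)
print(f"{len(dmrs)} DMRs called, {len(out.kept)} kept, "
      f"{len(out.dropped)} dropped by the monotonicity chains")
```

prints

```
conversion 99.50%
127 DMRs called, 85 kept, 42 dropped by the monotonicity chains
```

i.e. the spike-in recovers the simulated 99.5% bisulfite conversion, the
caller finds 127 regions between the strongest treatment and the pUC19
control, and the inequality chains discard 42 of them as inconsistent with
a dose- and gRNA-dependent enzyme effect. The kept hypermethylated DMRs
fall overwhelmingly in promoters/CpG islands/DHSs and carry elevated
gRNA-seed–PAM density, while kept hypomethylated DMRs concentrate in
Alu/LINE1 repeats — the qualitative off-target signature of an open-
chromatin-biased, seed-match-guided enzyme.

The same pipeline runs from the shell:

```
guidemeth simulate --seed 1 --out-dir run/
guidemeth call-dmrs --run-dir run/ --group-a 1 --group-b 9 --out run/dmrs.tsv
guidemeth filter-dmrs --run-dir run/ --dmrs run/dmrs.tsv --design uPA --out-prefix run/filtered
guidemeth enrich --run-dir run/ --regions run/kept.bed --out run/enrichment.tsv
guidemeth density --run-dir run/ --regions run/kept.bed --out run/density.tsv
guidemeth overlap --run-dir run/ --dmrs run/dmrs.tsv
```

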