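# asmscan

A tested, reusable pipeline that joins brain allele-specific-methylation
(ASM) catalogs — tables of SNP–CpG pairs with per-pair methylation
correlation R² — to GWAS summary statistics, and asks which risk variants
plausibly act through methylation:

1. **asm_catalog** — merge multi-study/multi-tissue SNP–CpG tables with
   provenance, filter (cis, R² ≥ 0.2 inclusive, autosomes), and check CpG
   probe footprints for colliding variants.
2. **ld_toolkit** — r²/|D′| from phased haplotype panels (exact counting)
   or unphased dosages (EM), greedy per-CpG tagSNP selection (r² ≥ 0.85),
   LD expansion of significant tags, LD blocks as connected components,
   and the effective number of independent tests from the eigenvalues of
   the variant correlation matrix.
3. **association_screen** — daner-style sumstats I/O, allele
   harmonization (swap / strand flip, ambiguous pairs dropped), one-sided
   Fisher enrichment over a threshold ladder (5e-2 … 5e-8), Storey
   q-values with smoothed π0 (BH fallback below 100 tests), and the three
   multiple-testing regimes (5% FDR / Bonferroni / Meff).
4. **functional_integration** — risk-allele orientation, strand-aware
   promoter mapping (< 5000 bp upstream of a TSS), methylation/expression
   inverse-direction verdicts, histone-mark counting over ten brain
   regions, brain-volume lookups with a per-run Bonferroni denominator,
   and per-LD-block prioritization of a putative causal variant.
5. **synthetic_data** — generates every input with known ground truth
   (block-LD panel, multi-source catalogs, enrichment-injected sumstats,
   annotation tables) plus a manifest that predicts all downstream
   outputs exactly.
6. **pipeline_cli** — one-config orchestration with per-stage TSV outputs,
   JSON parameter sidecars, and a flow-count summary.

## CLI

```bash
asmscan demo --seed 42 --out demo_dir          # simulate + full pipeline
asmscan simulate --config sim.toml --out sim   # synthetic inputs + manifest
asmscan run --config run.toml --out run        # pipeline on existing files
asmscan ld r2 --panel panel.vcf --a rs1 --b rs2
asmscan ld tags --panel panel.vcf --catalog filtered.tsv --out tags.tsv
asmscan ld expand --panel panel.vcf --catalog filtered.tsv --tags rs1,rs2 --out exp.tsv
asmscan ld meff --panel panel.vcf --snps rs1,rs2,rs3
asmscan screen run --sumstats ss.tsv --tags tags.tsv --out screen.tsv
asmscan integrate run --screen screen.tsv --annotations inputs/ --out report.tsv
```

`run.toml` is flat TOML; unknown keys are hard errors and every default
matches the published thresholds (`min_r2_meth = 0.2`, `tag_r2 = 0.85`,
`alpha = 0.05`, `promoter_window = 5000`). Required keys: `panel`
(VCF or hap TSV), `catalogs` (list of TSVs), `sumstats`, `annotations`
(directory holding `tss.tsv`, `histone.tsv`, `eqtl.tsv`, `volume.tsv`).

## File formats

All inputs and outputs are plain text: phased VCF or a haplotype-matrix
TSV for the reference panel, headered TSVs for catalogs/annotations
(1-based coordinates, chromosome labels accepted with or without a
`chr` prefix), daner-style sumstats (CHR SNP BP A1 A2 OR SE P), and JSON
for parameters/manifests.
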