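# ibdtrace

Identity-by-descent (IBD) analysis of a rare autosomal-dominant allele on
synthetic pedigree cohorts with fully known truth. The package implements an
end-to-end chain:

1. **simdata** — synthetic study generation: genetic map + marker panel,
   forward pedigree simulation, gene dropping with Poisson (Haldane)
   recombination and founder-segment truth labels, a planted rare dominant
   allele, an unrelated background cohort, skewed ancestry annotations and
   genealogical birth records tracing a planted three-epoch migration.
2. **ibd** — unphased IBD segment detection by seeded haplotype word matching
   with extension to the first opposite-homozygote marker, a brute-force
   oracle, and threshold-based match-set construction (strict > 6 cM
   genome-wide, strict > 1 cM across the focal locus window).
3. **network** — IBD-sharing network, meioses estimation from total shared
   genome fraction (`f = k * 2^-M`), degree-of-sharing profiles against a
   panel of known carriers, the all-carriers putative-carrier rule,
   evaluation against truth, and penetrance arithmetic.
4. **ancestry** — one-sided Mann–Whitney U enrichment of ethnicity
   proportions and Bonferroni-corrected hypergeometric enrichment of
   community labels.
5. **geomaps** — time-binned ([1700,1800), [1800,1850), [1850,1910])
   birth-location odds-ratio maps over unique-tree 2×2 tables with
   Haldane–Anscombe correction, plus a coarse small-set mode; GeoJSON/CSV
   export.
6. **age** — allele age (TMRCA) estimation from shared-haplotype flank
   lengths (recombination clock, Exp(2t)) and pair-private derived-allele
   counts (mutation clock, Poisson(2tμL)), combined on a log-spaced grid
   under a pairwise coalescent prior; control-doubleton discovery and age
   ranking.
7. **pipeline / cli** — configuration-driven orchestration with per-stage
   seeds and a machine-readable `report.json`.

## CLI

```bash
# full study from a JSON config (see configs/default_study.json)
ibdtrace run-all --config configs/default_study.json --out scratch/run1

# or stage by stage
ibdtrace simulate --config configs/default_study.json --out scratch/study
ibdtrace detect   --study scratch/study --min-cm 1 --out scratch/segments.match
ibdtrace classify --study scratch/study --matches scratch/segments.match \
                  --carriers P00012,P00034 --out scratch/calls.csv
ibdtrace enrich   --study scratch/study --group P00012,P00034 --out scratch/enrich.json
ibdtrace geomap   --study scratch/study --group P00012,P00034 --out scratch/map.geojson
ibdtrace age      --study scratch/study --pair P00012,P00034 --out scratch/age.json
```

All stage outputs are plain text (VCF 4.2, TSV/CSV, GeoJSON, GraphML, JSON).

## Notes on conventions

- Segment thresholds are strict inequalities (`> 6 cM`, `> 1 cM`).
- Shared-genome fraction is diploid-normalized (full siblings ≈ 0.5).
- Detection is seeded on phased haplotype words but extended and reported at
  genotype level; reported segments are unphased.
- Year bins are left-closed/right-open except the final bin, which includes
  1910; odds ratios count unique family trees, not raw records.
- Credible intervals on allele age are equal-tailed with their mass stated
  explicitly (`interval_mass = 0.975`).
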