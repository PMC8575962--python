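{
 "age_clock": "recombination",
 "background_size": 2000,
 "chrom_length_cm": 150.0,
 "community_alpha": 0.001,
 "detect_min_cm": 1.0,
 "ethnicity_alpha": 0.05,
 "focal_chrom": "chr1",
 "focal_cm": 75.0,
 "freq_max": 0.95,
 "freq_min": 0.05,
 "generation_time": 25.0,
 "genome_threshold_cm": 6.0,
 "genotype_error_rate": 0.0,
 "geo_min_or": 4.0,
 "geo_min_trees": 10,
 "geo_rounding": 0,
 "ibs_filter": false,
 "known_carrier_min_generation": 4,
 "locus_threshold_cm": 1.0,
 "max_ascertainment_attempts": 200,
 "max_hom_mismatches": 0,
 "max_pedigree_size": 3000,
 "mean_offspring": 2.5,
 "min_fold": 1.5,
 "mut_rate": 1.25e-08,
 "n_chromosomes": 3,
 "n_generations": 8,
 "n_known_carriers": 5,
 "n_markers_per_chrom": 3000,
 "ne": 10000.0,
 "null_annotations": false,
 "recomb_rate": 1e-08,
 "scatter_sd_deg": 0.5,
 "seed": 1,
 "small_set_min_trees": 2,
 "window_half_cm": 2.0,
 "word_size": 64
}
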