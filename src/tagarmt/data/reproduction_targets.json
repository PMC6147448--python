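{
  "schema_version": 1,
  "comment": "Expected values of the headline descriptive statistics of the bundled Iron Age series, with comparison tolerances. Percentages are on the 0-100 scale; tolerances reflect one-decimal reporting except where noted.",
  "targets": [
    {"key": "n_samples", "expected": 79, "tol": 0, "description": "individuals with an HVRI haplotype"},
    {"key": "n_early", "expected": 46, "tol": 0, "description": "Early-stage sample size"},
    {"key": "n_middle", "expected": 24, "tol": 0, "description": "Middle-stage sample size"},
    {"key": "n_late", "expected": 9, "tol": 0, "description": "Late-stage sample size"},
    {"key": "n_distinct_haplotypes", "expected": 39, "tol": 0, "description": "distinct HVRI haplotypes"},
    {"key": "n_singleton_haplotypes", "expected": 22, "tol": 0, "description": "haplotypes carried by a single individual"},
    {"key": "modal_haplotype_count", "expected": 10, "tol": 0, "description": "carriers of the most frequent haplotype (T1 root motif)"},
    {"key": "pct_west_overall", "expected": 64.6, "tol": 0.05, "description": "West Eurasian share of all samples (%)"},
    {"key": "pct_east_overall", "expected": 35.4, "tol": 0.05, "description": "East Eurasian share of all samples (%)"},
    {"key": "pct_east_early", "expected": 34.8, "tol": 0.05, "description": "East Eurasian share of the Early stage (%)"},
    {"key": "pct_east_middle", "expected": 45.8, "tol": 0.05, "description": "East Eurasian share of the Middle stage (%)"},
    {"key": "late_west_count", "expected": 8, "tol": 0, "description": "West Eurasian individuals among the 9 Late-stage samples"},
    {"key": "pct_t1", "expected": 13.9, "tol": 0.05, "description": "haplogroup T1 frequency (%)"},
    {"key": "pct_u4", "expected": 10.1, "tol": 0.05, "description": "haplogroup U4 frequency incl. nested sub-clades (%)"},
    {"key": "pct_a8", "expected": 10.1, "tol": 0.05, "description": "haplogroup A8 frequency (%)"},
    {"key": "pct_cd_early", "expected": 8.7, "tol": 0.05, "description": "joint C+D frequency in the Early stage (%)"},
    {"key": "pct_cd_middle", "expected": 37.5, "tol": 0.05, "description": "joint C+D frequency in the Middle stage (%)"},
    {"key": "pct_middle_individuals_in_early", "expected": 50.0, "tol": 0.05, "description": "Middle-stage individuals carrying a haplotype present in the Early stage (%)"},
    {"key": "early_distinct_haplotypes", "expected": 29, "tol": 0, "description": "distinct haplotypes in the Early stage"},
    {"key": "early_haplotypes_missing_from_middle", "expected": 23, "tol": 0, "description": "Early-stage haplotypes absent from the Middle stage"},
    {"key": "pct_early_individuals_missing_from_middle", "expected": 72, "tol": 0.5, "description": "Early-stage individuals whose haplotype is absent from the Middle stage (%, printed to integer precision)"},
    {"key": "min_detectable_freq_n16", "expected": 0.171, "tol": 0.0005, "description": "minimum detectable cluster frequency, N=16, alpha=0.05"},
    {"key": "min_detectable_freq_n24", "expected": 0.117, "tol": 0.0005, "description": "minimum detectable cluster frequency, N=24, alpha=0.05"},
    {"key": "min_detectable_freq_n46", "expected": 0.063, "tol": 0.0005, "description": "minimum detectable cluster frequency, N=46, alpha=0.05"},
    {"key": "min_detectable_freq_n79", "expected": 0.037, "tol": 0.0005, "description": "minimum detectable cluster frequency, N=79, alpha=0.05"},
    {"key": "caller_concordant", "expected": 79, "tol": 0, "description": "samples whose motif-table haplogroup call equals the curated label"}
  ]
}
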