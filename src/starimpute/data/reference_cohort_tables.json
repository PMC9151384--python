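{
  "_comment": "Published summary tables from the Finnish cohort studies this package's methodology was validated on, transcribed from the printed reports. cnv_validation_contingency: real-time-PCR-genotyped (rows, CN 1-4) vs imputed (columns, CN 1-3) CYP2D6 copy number in the 304-sample validation subset. um_validation: CYP2D6 ultrarapid-metabolizer concordance counts (imputed UMs with both imputation and genotyping results; ambiguous duplication calls assigned pessimistically to NM). region_sizes / um prevalences: recruitment-region sample sizes and reported regional CYP2D6 UM prevalences. phenotype_counts: predicted-phenotype counts per gene in the full cohort (n = 9262). allele_frequencies: reported minor-allele frequencies in Finns vs non-Finnish Europeans.",
  "cnv_validation_contingency": {
    "genotyped_classes": [1, 2, 3, 4],
    "imputed_classes": [1, 2, 3],
    "counts": [
      [32, 3, 1],
      [9, 172, 11],
      [0, 1, 74],
      [0, 0, 1]
    ]
  },
  "um_validation": {
    "n_with_both_results": 55,
    "n_confirmed_um": 52,
    "n_ambiguous_pessimistic_nm": 3
  },
  "cohort_n": 9262,
  "region_sizes": {
    "Helsinki": 2329,
    "Tampere": 2298,
    "Kuopio": 1886,
    "Oulu": 1736,
    "Turku": 1013
  },
  "cyp2d6_um_prevalence_by_region_pct": {
    "Kuopio": 5.0,
    "Oulu": 7.7
  },
  "phenotype_counts": {
    "CYP2C9": {"Normal": 6230, "Intermediate (AS 1.5)": 1823, "Intermediate (AS 1.0)": 1022, "Poor": 187},
    "CYP2C19": {"Ultrarapid": 355, "Rapid": 2254, "Normal": 3676, "Intermediate": 2656, "Poor": 321},
    "CYP2D6": {"Ultrarapid": 607, "Normal": 5811, "Intermediate": 2545, "Poor": 299},
    "DPYD": {"Normal": 8604, "Intermediate (AS 1.5)": 242, "Intermediate (AS 1)": 403, "Poor (AS 0.5)": 5, "Poor (AS 0)": 8},
    "NUDT15": {"Normal": 8915, "Intermediate": 336, "Poor": 11},
    "SLCO1B1": {"Normal": 5795, "Decreased": 3110, "Poor": 357},
    "TPMT": {"Normal": 8712, "Intermediate": 539, "Poor": 11},
    "UGT1A1": {"Normal": 2949, "Intermediate": 4522, "Poor": 1791}
  },
  "allele_frequencies": {
    "rs116855232": {"finnish": 0.02, "non_finnish_european": 0.004},
    "rs4148323": {"finnish": 0.05, "non_finnish_european": 0.002}
  }
}
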