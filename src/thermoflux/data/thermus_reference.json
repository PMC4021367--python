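{
  "organism": "Thermus thermophilus HB27",
  "model_gene_count": 548,
  "model_reaction_count": 796,
  "model_metabolite_count": 635,
  "genome_orf_count": 2263,
  "od600_to_dcw_g_per_l": 0.34,
  "gc_content": 0.694,
  "gam_atp_mmol_per_gdcw": 58.34,
  "ngam_mmol_per_gdcw_h": 14.0,
  "oxygen_uptake_mmol_per_gdcw_h": 10.0,
  "essentiality_threshold": 0.05
}
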