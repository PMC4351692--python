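{
  "name": "pfluorescens_sbw25_fructose_reduced",
  "n_metabolites": 28,
  "n_balanced": 25,
  "n_reactions": 34,
  "n_reversible": 13,
  "free_net_dim": 9,
  "free_net_candidates": ["upt", "bm", "f1pa", "fbp", "gnd", "icl", "mae", "pc", "ppc"],
  "free_exchange": ["pgi", "fba", "tpi", "gapd", "mdh", "fum"],
  "biomass_reaction": "bm",
  "uptake_reaction": "upt",
  "co2_reaction": "co2_out",
  "biomass_carbon_mmolC_per_gDW": 35.0,
  "notes": {
    "provenance": "Reduced reconstruction of the published full-scale central-carbon model for this organism (reported as 66 metabolites, 116 reactions, 18 reversible, 29 degrees of freedom split as 13 net + 15 exchange; note that 13 + 15 = 28, an internal discrepancy of the reported counts). This packaged model lumps pools and pathways down to the counts recorded here; its own free dimensions are 9 net + 6 exchange.",
    "free_exchange_note": "Only the listed reversible reactions carry free exchange fluxes in fitting; the remaining reversible reactions are held at zero exchange."
  }
}
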