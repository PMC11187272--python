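{
  "provisional": true,
  "note": "Mapping between the abbreviation style used in the field (side 'S'/top 'T' prefixes) and this package's canonical feature keys. The original abbreviation definitions are not public; assignments below are the package's documented best reading and may be remapped without code changes.",
  "texture": {
    "SMG": "side_texture_T1",
    "SGD": "side_texture_T4",
    "SIG1": "side_texture_sigma1",
    "SIG2": "side_texture_sigma2",
    "SE": "side_texture_T3",
    "SG": "side_texture_mu1",
    "SGA": "side_texture_mu2",
    "SGE1": "side_texture_T5",
    "SGE2": "side_texture_T6",
    "SME": "side_texture_T7",
    "SDM": "side_texture_T8",
    "SHE": "side_texture_Hhist",
    "TGD": "top_texture_T4",
    "TE": "top_texture_T3",
    "TG": "top_texture_mu1",
    "TGE1": "top_texture_T5",
    "TME": "top_texture_T7",
    "TDM": "top_texture_T8",
    "TGH": "top_texture_S2",
    "THE": "top_texture_Hhist"
  },
  "morphology": {
    "SPA1": "side_morph_area",
    "SCA1": "side_morph_convex_area",
    "1/5MW": "side_morph_width_1_5",
    "2/5MW": "side_morph_width_2_5",
    "3/5MW": "side_morph_width_3_5",
    "4/5MW": "side_morph_width_4_5",
    "SMW": "side_morph_mean_width",
    "SMIW": "side_morph_min_width",
    "SRA": "side_morph_extent",
    "SSC": "side_morph_circularity",
    "SPA2": "side_morph_perimeter",
    "SCA": "side_morph_convex_perimeter",
    "TC2": "side_morph_aspect_ratio",
    "TPA1": "top_morph_area",
    "TCA1": "top_morph_convex_area",
    "TRW": "top_morph_bbox_width",
    "TRH": "top_morph_bbox_height",
    "TCR": "top_morph_circularity",
    "TRA": "top_morph_extent",
    "TCA2": "top_morph_aspect_ratio",
    "TSC": "top_morph_solidity",
    "TCA3": "top_morph_equivalent_diameter"
  }
}
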