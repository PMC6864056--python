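{
 "microns_per_pixel": 0.5,
 "min_region_area": 50.0,
 "features": {
  "fat_amount": 253.25,
  "fat_amount_norm": 31.178824253616497,
  "stroma_amount": 356.75,
  "stroma_amount_norm": 43.92120652508464,
  "epi_amount": 202.25,
  "epi_amount_norm": 24.89996922129886,
  "n_epi_regions": 3.0,
  "epi_area_mean": 67.41666666666667,
  "epi_area_median": 58.25,
  "epi_area_sd": 15.319287044623048,
  "epi_area_iq": 17.0,
  "epi_area_max": 89.0,
  "epi_ecc_mean": 0.7331790025951804,
  "epi_ecc_median": 0.7195419163887902,
  "epi_ecc_sd": 0.028746732058684388,
  "epi_ecc_iq": 0.03316751898967274,
  "epi_ecc_max": 0.7731650646880484,
  "voronoi_area_mean": 270.75,
  "voronoi_area_median": 237.0,
  "voronoi_area_sd": 63.73087948553668,
  "voronoi_area_iq": 72.375,
  "voronoi_area_max": 360.0,
  "ratio_epi_voronoi_mean": 0.2691152574199039,
  "ratio_epi_voronoi_median": 0.2320675105485232,
  "ratio_epi_voronoi_sd": 0.10602983961751816,
  "ratio_epi_voronoi_iq": 0.1258335753000387,
  "ratio_epi_voronoi_max": 0.413472706155633,
  "ratio_epi_nonepi_mean": 0.40006296458920176,
  "ratio_epi_nonepi_median": 0.3021978021978022,
  "ratio_epi_nonepi_sd": 0.22014560115291412,
  "ratio_epi_nonepi_iq": 0.2559549492646034,
  "ratio_epi_nonepi_max": 0.7049504950495049,
  "delaunay_neighbors_mean": 2.0,
  "delaunay_neighbors_median": 2.0,
  "delaunay_neighbors_sd": 0.0,
  "delaunay_neighbors_iq": 0.0,
  "delaunay_neighbors_max": 2.0,
  "no_epithelium": 0.0
 }
}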