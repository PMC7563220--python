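[
  {"tissue_id": "applicator_shell", "eps_r": 2.0, "sigma_eff": 0.004, "rho": 1180},
  {"tissue_id": "water", "eps_r": 80.9, "sigma_eff": 0.002, "rho": 1000},
  {"tissue_id": "fat", "eps_r": 12.7, "sigma_eff": 0.007, "rho": 911},
  {"tissue_id": "muscle", "eps_r": 66.0, "sigma_eff": 0.708, "rho": 1090},
  {"tissue_id": "cortical_bone", "eps_r": 15.3, "sigma_eff": 0.006, "rho": 1908},
  {"tissue_id": "bone_marrow", "eps_r": 14.3, "sigma_eff": 0.159, "rho": 1029},
  {"tissue_id": "cancellous_bone", "eps_r": 27.6, "sigma_eff": 0.173, "rho": 1178},
  {"tissue_id": "small_intestine_wall", "eps_r": 96.5, "sigma_eff": 1.660, "rho": 1030},
  {"tissue_id": "small_intestine_lumen", "eps_r": 80.0, "sigma_eff": 2.000, "rho": 1000},
  {"tissue_id": "large_intestine_wall", "eps_r": 81.8, "sigma_eff": 0.680, "rho": 1088},
  {"tissue_id": "large_intestine_lumen", "eps_r": 66.0, "sigma_eff": 0.708, "rho": 1090},
  {"tissue_id": "bladder_wall", "eps_r": 22.7, "sigma_eff": 0.294, "rho": 1086},
  {"tissue_id": "urine", "eps_r": 49.9, "sigma_eff": 1.750, "rho": 1024},
  {"tissue_id": "gtv", "eps_r": 70.0, "sigma_eff": 0.750, "rho": 1050}
]
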