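{
  "version": "1.0",
  "field_strength_mhz": 123.25,
  "description": "Parametric 1H multiplet models for single-voxel brain/cord MRS at 3 T. Each line is [chemical shift (ppm), proton-weighted relative intensity]. Intensities sum to the number of observable protons per molecule. Chemical shifts follow standard literature compilations; base_lorentz_lw_hz is the intrinsic Lorentzian FWHM of each metabolite's lines before shim (Gauss) broadening. t1_ms / t2_ms are literature-style relaxation times at 3 T used for saturation and T2-loss corrections; they are configuration values, not measurements.",
  "metabolites": {
    "Asp": {
      "full_name": "aspartate",
      "lines": [[2.654, 1.0], [2.801, 1.0], [3.891, 1.0]],
      "base_lorentz_lw_hz": 3.0,
      "t1_ms": 1400.0,
      "t2_ms": 180.0,
      "default_conc_mm": 1.5
    },
    "Cr": {
      "full_name": "creatine",
      "lines": [[3.027, 3.0], [3.913, 2.0]],
      "base_lorentz_lw_hz": 2.5,
      "t1_ms": 1330.0,
      "t2_ms": 162.0,
      "default_conc_mm": 4.5
    },
    "GABA": {
      "full_name": "gamma-aminobutyric acid",
      "lines": [[1.889, 2.0], [2.284, 2.0], [3.013, 2.0]],
      "base_lorentz_lw_hz": 4.0,
      "t1_ms": 1310.0,
      "t2_ms": 180.0,
      "default_conc_mm": 1.3
    },
    "Glc": {
      "full_name": "glucose",
      "lines": [[3.23, 1.0], [3.40, 1.0], [3.47, 1.0], [3.52, 1.0], [3.73, 1.5], [3.82, 1.0], [5.223, 0.5]],
      "base_lorentz_lw_hz": 4.0,
      "t1_ms": 1200.0,
      "t2_ms": 180.0,
      "default_conc_mm": 1.2
    },
    "Glu": {
      "full_name": "glutamate",
      "lines": [[2.042, 1.0], [2.120, 1.0], [2.336, 1.0], [2.352, 1.0], [3.746, 1.0]],
      "base_lorentz_lw_hz": 3.5,
      "t1_ms": 1270.0,
      "t2_ms": 180.0,
      "default_conc_mm": 9.0
    },
    "Gln": {
      "full_name": "glutamine",
      "lines": [[2.109, 1.0], [2.129, 1.0], [2.432, 1.0], [2.454, 1.0], [3.757, 1.0]],
      "base_lorentz_lw_hz": 3.5,
      "t1_ms": 1270.0,
      "t2_ms": 180.0,
      "default_conc_mm": 3.0
    },
    "GSH": {
      "full_name": "glutathione",
      "lines": [[2.159, 1.0], [2.510, 1.0], [2.926, 1.0], [2.975, 1.0], [3.769, 1.0]],
      "base_lorentz_lw_hz": 4.0,
      "t1_ms": 1300.0,
      "t2_ms": 180.0,
      "default_conc_mm": 2.0
    },
    "Gly": {
      "full_name": "glycine",
      "lines": [[3.548, 2.0]],
      "base_lorentz_lw_hz": 3.0,
      "t1_ms": 1300.0,
      "t2_ms": 180.0,
      "default_conc_mm": 1.0
    },
    "GPC": {
      "full_name": "glycerophosphorylcholine",
      "lines": [[3.212, 9.0], [3.605, 1.0], [3.672, 1.0], [4.312, 2.0]],
      "base_lorentz_lw_hz": 2.5,
      "t1_ms": 1140.0,
      "t2_ms": 207.0,
      "default_conc_mm": 1.0
    },
    "Lac": {
      "full_name": "lactate",
      "lines": [[1.313, 3.0], [4.097, 1.0]],
      "base_lorentz_lw_hz": 3.0,
      "t1_ms": 1550.0,
      "t2_ms": 240.0,
      "default_conc_mm": 0.6
    },
    "mI": {
      "full_name": "myo-inositol",
      "lines": [[3.522, 2.0], [3.614, 2.0], [3.269, 1.0], [4.054, 1.0]],
      "base_lorentz_lw_hz": 3.0,
      "t1_ms": 1010.0,
      "t2_ms": 196.0,
      "default_conc_mm": 6.5
    },
    "NAA": {
      "full_name": "N-acetylaspartate",
      "lines": [[2.008, 3.0], [2.486, 1.0], [2.673, 1.0], [4.382, 1.0]],
      "base_lorentz_lw_hz": 2.5,
      "t1_ms": 1470.0,
      "t2_ms": 247.0,
      "default_conc_mm": 12.0
    },
    "NAAG": {
      "full_name": "N-acetylaspartylglutamate",
      "lines": [[2.042, 3.0], [2.52, 1.0], [2.72, 1.0], [4.38, 1.0]],
      "base_lorentz_lw_hz": 3.5,
      "t1_ms": 1470.0,
      "t2_ms": 247.0,
      "default_conc_mm": 1.5
    },
    "PCr": {
      "full_name": "phosphocreatine",
      "lines": [[3.029, 3.0], [3.930, 2.0]],
      "base_lorentz_lw_hz": 2.5,
      "t1_ms": 1330.0,
      "t2_ms": 162.0,
      "default_conc_mm": 3.5
    },
    "PCho": {
      "full_name": "phosphorylcholine",
      "lines": [[3.208, 9.0], [3.643, 2.0], [4.282, 2.0]],
      "base_lorentz_lw_hz": 2.5,
      "t1_ms": 1140.0,
      "t2_ms": 207.0,
      "default_conc_mm": 0.6
    },
    "PE": {
      "full_name": "phosphorylethanolamine",
      "lines": [[3.221, 2.0], [3.977, 2.0]],
      "base_lorentz_lw_hz": 4.0,
      "t1_ms": 1300.0,
      "t2_ms": 180.0,
      "default_conc_mm": 1.5
    },
    "sI": {
      "full_name": "scyllo-inositol",
      "lines": [[3.340, 6.0]],
      "base_lorentz_lw_hz": 2.5,
      "t1_ms": 1200.0,
      "t2_ms": 200.0,
      "default_conc_mm": 0.3
    },
    "Tau": {
      "full_name": "taurine",
      "lines": [[3.246, 2.0], [3.420, 2.0]],
      "base_lorentz_lw_hz": 3.5,
      "t1_ms": 1500.0,
      "t2_ms": 200.0,
      "default_conc_mm": 1.5
    }
  },
  "water": {
    "full_name": "water",
    "ppm": 4.68,
    "protons": 2.0,
    "base_lorentz_lw_hz": 4.0,
    "t1_ms": 1100.0
  },
  "mmbg_truth": {
    "description": "Ground-truth macromolecular background used by the simulator: broad Voigt components at standard MM positions; amplitudes are per unit mmbg_scale in the same signal units as a 1 mM proton-weighted metabolite.",
    "lines": [[0.91, 4.0], [1.21, 3.0], [1.43, 2.0], [1.72, 2.0], [2.05, 3.5], [2.29, 2.5], [3.00, 2.0], [3.21, 1.5], [3.77, 2.5]],
    "lorentz_lw_hz": 45.0
  }
}
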