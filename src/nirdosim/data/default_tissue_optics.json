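{
  "_comment": "Default tissue optical properties at the five treatment wavelengths. Units: mua, mus in 1/mm; g, n dimensionless. These are literature-plausible stand-ins compiled from standard tissue-optics surveys (head tissues at red/NIR wavelengths; water-dominated media follow the water absorption spectrum with its 980 nm peak). They are configurable defaults, not measured constants.",
  "gray_matter": {
    "670":  {"mua": 0.030, "mus": 10.9, "g": 0.89, "n": 1.37},
    "810":  {"mua": 0.019, "mus": 9.1,  "g": 0.89, "n": 1.37},
    "850":  {"mua": 0.019, "mus": 8.6,  "g": 0.89, "n": 1.37},
    "980":  {"mua": 0.024, "mus": 7.7,  "g": 0.89, "n": 1.37},
    "1070": {"mua": 0.021, "mus": 7.3,  "g": 0.89, "n": 1.37}
  },
  "white_matter": {
    "670":  {"mua": 0.090, "mus": 42.0, "g": 0.84, "n": 1.38},
    "810":  {"mua": 0.080, "mus": 41.0, "g": 0.84, "n": 1.38},
    "850":  {"mua": 0.075, "mus": 40.0, "g": 0.84, "n": 1.38},
    "980":  {"mua": 0.080, "mus": 38.0, "g": 0.84, "n": 1.38},
    "1070": {"mua": 0.080, "mus": 36.0, "g": 0.84, "n": 1.38}
  },
  "csf": {
    "670":  {"mua": 0.0005, "mus": 0.10, "g": 0.89, "n": 1.33},
    "810":  {"mua": 0.0022, "mus": 0.10, "g": 0.89, "n": 1.33},
    "850":  {"mua": 0.0043, "mus": 0.10, "g": 0.89, "n": 1.33},
    "980":  {"mua": 0.0480, "mus": 0.10, "g": 0.89, "n": 1.33},
    "1070": {"mua": 0.0170, "mus": 0.10, "g": 0.89, "n": 1.33}
  },
  "skull": {
    "670":  {"mua": 0.020, "mus": 18.0, "g": 0.90, "n": 1.43},
    "810":  {"mua": 0.012, "mus": 15.0, "g": 0.90, "n": 1.43},
    "850":  {"mua": 0.012, "mus": 14.5, "g": 0.90, "n": 1.43},
    "980":  {"mua": 0.022, "mus": 13.0, "g": 0.90, "n": 1.43},
    "1070": {"mua": 0.022, "mus": 12.0, "g": 0.90, "n": 1.43}
  },
  "soft_tissue": {
    "670":  {"mua": 0.025, "mus": 18.0, "g": 0.90, "n": 1.37},
    "810":  {"mua": 0.019, "mus": 15.0, "g": 0.90, "n": 1.37},
    "850":  {"mua": 0.020, "mus": 14.0, "g": 0.90, "n": 1.37},
    "980":  {"mua": 0.030, "mus": 12.0, "g": 0.90, "n": 1.37},
    "1070": {"mua": 0.028, "mus": 11.0, "g": 0.90, "n": 1.37}
  },
  "air": {
    "670":  {"mua": 0.0, "mus": 0.0, "g": 0.0, "n": 1.0},
    "810":  {"mua": 0.0, "mus": 0.0, "g": 0.0, "n": 1.0},
    "850":  {"mua": 0.0, "mus": 0.0, "g": 0.0, "n": 1.0},
    "980":  {"mua": 0.0, "mus": 0.0, "g": 0.0, "n": 1.0},
    "1070": {"mua": 0.0, "mus": 0.0, "g": 0.0, "n": 1.0}
  },
  "eyelid_skin": {
    "670":  {"mua": 0.028, "mus": 16.0, "g": 0.90, "n": 1.37},
    "810":  {"mua": 0.021, "mus": 13.5, "g": 0.90, "n": 1.37},
    "850":  {"mua": 0.022, "mus": 13.0, "g": 0.90, "n": 1.37},
    "980":  {"mua": 0.032, "mus": 11.5, "g": 0.90, "n": 1.37},
    "1070": {"mua": 0.030, "mus": 10.5, "g": 0.90, "n": 1.37}
  },
  "cornea": {
    "670":  {"mua": 0.0016, "mus": 1.0, "g": 0.90, "n": 1.376},
    "810":  {"mua": 0.0026, "mus": 0.9, "g": 0.90, "n": 1.376},
    "850":  {"mua": 0.0045, "mus": 0.9, "g": 0.90, "n": 1.376},
    "980":  {"mua": 0.0460, "mus": 0.8, "g": 0.90, "n": 1.376},
    "1070": {"mua": 0.0170, "mus": 0.8, "g": 0.90, "n": 1.376}
  },
  "aqueous": {
    "670":  {"mua": 0.0005, "mus": 0.05, "g": 0.90, "n": 1.336},
    "810":  {"mua": 0.0022, "mus": 0.05, "g": 0.90, "n": 1.336},
    "850":  {"mua": 0.0043, "mus": 0.05, "g": 0.90, "n": 1.336},
    "980":  {"mua": 0.0480, "mus": 0.05, "g": 0.90, "n": 1.336},
    "1070": {"mua": 0.0170, "mus": 0.05, "g": 0.90, "n": 1.336}
  },
  "lens": {
    "670":  {"mua": 0.0045, "mus": 3.0, "g": 0.92, "n": 1.41},
    "810":  {"mua": 0.0050, "mus": 2.6, "g": 0.92, "n": 1.41},
    "850":  {"mua": 0.0065, "mus": 2.5, "g": 0.92, "n": 1.41},
    "980":  {"mua": 0.0400, "mus": 2.2, "g": 0.92, "n": 1.41},
    "1070": {"mua": 0.0180, "mus": 2.0, "g": 0.92, "n": 1.41}
  },
  "vitreous": {
    "670":  {"mua": 0.0005, "mus": 0.05, "g": 0.90, "n": 1.336},
    "810":  {"mua": 0.0022, "mus": 0.05, "g": 0.90, "n": 1.336},
    "850":  {"mua": 0.0043, "mus": 0.05, "g": 0.90, "n": 1.336},
    "980":  {"mua": 0.0480, "mus": 0.05, "g": 0.90, "n": 1.336},
    "1070": {"mua": 0.0170, "mus": 0.05, "g": 0.90, "n": 1.336}
  },
  "orbital_fat": {
    "670":  {"mua": 0.010, "mus": 12.0, "g": 0.92, "n": 1.44},
    "810":  {"mua": 0.010, "mus": 11.0, "g": 0.92, "n": 1.44},
    "850":  {"mua": 0.011, "mus": 10.5, "g": 0.92, "n": 1.44},
    "980":  {"mua": 0.020, "mus": 10.0, "g": 0.92, "n": 1.44},
    "1070": {"mua": 0.018, "mus": 9.5,  "g": 0.92, "n": 1.44}
  },
  "muscle": {
    "670":  {"mua": 0.050, "mus": 9.0, "g": 0.90, "n": 1.37},
    "810":  {"mua": 0.032, "mus": 7.5, "g": 0.90, "n": 1.37},
    "850":  {"mua": 0.033, "mus": 7.2, "g": 0.90, "n": 1.37},
    "980":  {"mua": 0.050, "mus": 6.5, "g": 0.90, "n": 1.37},
    "1070": {"mua": 0.045, "mus": 6.0, "g": 0.90, "n": 1.37}
  },
  "sclera_retina": {
    "670":  {"mua": 0.070, "mus": 30.0, "g": 0.90, "n": 1.38},
    "810":  {"mua": 0.055, "mus": 27.0, "g": 0.90, "n": 1.38},
    "850":  {"mua": 0.055, "mus": 26.0, "g": 0.90, "n": 1.38},
    "980":  {"mua": 0.070, "mus": 23.0, "g": 0.90, "n": 1.38},
    "1070": {"mua": 0.065, "mus": 21.0, "g": 0.90, "n": 1.38}
  }
}
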