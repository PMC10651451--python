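{
  "schema": "spipls-raw-linear-model",
  "description": "Portable raw-coefficient linear SPI calibration for Italian mono-varietal red wines: SPI (g/L GAE) = intercept + sum(coefficient * raw assay value). Coefficients are in response units per raw predictor unit, so inputs need no centering or scaling.",
  "response": "SPI (g/L GAE)",
  "intercept": 2.4385,
  "coefficients": {
    "Volatile acidity (g acetic acid/L)": 1.5492,
    "Tartaric acid (g/L)": 0.3903,
    "Titratable acidity (g tartaric acid/L)": 0.1844,
    "Absorbance 520 nm": 0.1102,
    "Procyanidin B1 (mg/L)": 0.0329,
    "Buffer capacity (meq/pH unit)": 0.0145,
    "Catechin terminal unit (mg/L)": 0.0068,
    "Epigallocatechin gallate PHL (mg/L)": 0.002,
    "Vanillin assay (mg catechin/L)": 0.0004,
    "Catechin + epicatechin PHL (mg/L)": 0.0003,
    "Proanthocyanidins assay (mg cyanidin chloride/L)": 0.0002,
    "Tannins-Fe (mg/L)": 0.0001,
    "Epigallocatechin PHL (mg/L)": -0.0016,
    "Polysaccharide content (mg/L)": -0.0017,
    "Total aldehydes (mg/L)": -0.0101,
    "Protein content (mg/L)": -0.0101,
    "Epicatechin terminal unit (mg/L)": -0.0221,
    "Tannin-Fe/Anthocyanin": -0.0337,
    "pH": -0.7919
  }
}
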