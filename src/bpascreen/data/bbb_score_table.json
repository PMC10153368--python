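{
  "version": "gupta-2019-v1",
  "provenance": "Blood-brain-barrier score of Gupta, Lee, Mobitz et al., J. Med. Chem. 2019, 62, 9824-9836; component polynomials and weights transcribed into editable data so they can be audited or substituted. Score = w_aro*P(Aro) + w_ha*P(HA) + w_mwhbn*P(MWHBN) + w_tpsa*P(TPSA) + w_pka*P(pKa), each P clamped to [0,1].",
  "weights": {
    "aromatic_rings": 1.0,
    "heavy_atoms": 1.0,
    "mwhbn": 1.5,
    "tpsa": 2.0,
    "pka": 0.5
  },
  "aromatic_rings_step": {
    "0": 0.336376,
    "1": 0.816016,
    "2": 1.0,
    "3": 0.691115,
    "4": 0.199399,
    "default": 0.0
  },
  "heavy_atoms": {
    "range": [5, 45],
    "poly": [0.0000443, -0.004556, 0.12775, -0.463],
    "scale": 0.624231
  },
  "mwhbn": {
    "range": [0.05, 0.45],
    "poly": [26.733, -31.495, 9.5202, -0.1358],
    "scale": 0.72258
  },
  "tpsa": {
    "range": [0, 120],
    "poly": [-0.0067, 0.9598],
    "scale": 0.9598
  },
  "pka": {
    "range": [3, 11],
    "poly": [0.00045068, -0.016331, 0.18618, -0.71043, 0.8579],
    "scale": 0.597488,
    "missing_policy": "zero"
  }
}
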