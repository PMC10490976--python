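{
  "IOLM": {
    "comment": "Right-eye (OD) regression from preoperative IOLM keratometric astigmatism components to postoperative CASIA real-power components, as published for this analysis.",
    "matrix": [[0.9150, -0.0472], [-0.0018, 0.6952]],
    "intercept": [-0.1823, -0.0229],
    "eye_side": "OD",
    "logL": -57.1781
  },
  "CASIA": {
    "comment": "Right-eye (OD) regression from preoperative CASIA keratometric astigmatism components to postoperative CASIA real-power components, as published for this analysis.",
    "matrix": [[1.0253, -0.0023], [-0.0473, 0.8774]],
    "intercept": [-0.2716, -0.2716],
    "eye_side": "OD",
    "logL": -37.8488
  }
}
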