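{
  "_comment": "Skull indices marked on the burr cross-section. default_angle_deg follows the left-antler convention: viewed along the pedicle axis from distal, 0 deg at the anterior pole, increasing toward the lateral side.",
  "indices": {
    "SR":   {"description": "supraorbital ridge on the pedicle", "default_angle_deg": 15.0},
    "TR":   {"description": "temporal ridge on the pedicle", "default_angle_deg": 130.0},
    "IFST": {"description": "impression of the frontal branch of the superficial temporal artery (medial branch)", "default_angle_deg": 345.0},
    "SPO":  {"description": "reaching the superior-posterior margin of the orbit", "default_angle_deg": 60.0},
    "LMOF": {"description": "reaching the lateral margin of the origin of the frontoscutular muscle, to the posterior margin of the orbit", "default_angle_deg": 100.0},
    "PEOI": {"description": "reaching the posterior extremity of the origin of the interscutular muscle", "default_angle_deg": 165.0},
    "BN":   {"description": "boundary of the supraorbital nerve area and the temporal nerve area", "default_angle_deg": 200.0}
  }
}
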