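{
 "melanoma_excise": 0.2,
 "malignancy_excise": 0.5,
 "bcc_excise": 0.4,
 "akiec_local": 0.4,
 "monitor": 0.1,
 "fallback_action": "DISMISS",
 "provenance": "synthetic consensus-style defaults (author-designed)"
}
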