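{
 "note": "Synthetic re-parameterisation of the PhoBR two-component-system networks: rate constants chosen within physiological E. coli ranges and calibrated to the documented dynamic regimes, not transcribed from a published table.",
 "models": {
  "full": {
   "file": "phobr_full.yaml",
   "sha256": "37dfb741eff889c1c1903e96800445b2123e4ba1c24ad983733470a1b329c039"
  },
  "reduced": {
   "file": "phobr_reduced.yaml",
   "sha256": "fdc5494b0224d62784c89d60a1333ab8ef249997fc8fc94d0747b905fbac8ecd"
  }
 },
 "reduced_derivation": "reduced constants derived from the full set by phobr.models.reduced_params_from_full with k3_multiplier=2"
}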