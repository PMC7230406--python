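{
  "version": "1.0",
  "comment": "Simplified nearest-neighbor stacking model used by all folding, consensus and duplex energies. Units are model kcal/mol. Stacked pair-on-pair energy is -(w_outer + w_inner)/2 from the pair weights below; a pair not flanked by a stacked neighbor contributes no stabilizing energy of its own.",
  "pair_weights": {
    "GC": 3.3,
    "CG": 3.3,
    "AU": 2.1,
    "UA": 2.1,
    "GU": 1.4,
    "UG": 1.4
  },
  "hairpin_base": 3.2,
  "hairpin_per_nt": 0.25,
  "min_hairpin_loop": 3,
  "bulge_base": 3.0,
  "bulge_per_nt": 0.4,
  "internal_base": 2.5,
  "internal_per_nt": 0.3,
  "max_interior_unpaired": 12,
  "multiloop_unpaired": 0.0,
  "consensus_covariation_bonus": 1.0,
  "consensus_nonpair_penalty": 1.5
}
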