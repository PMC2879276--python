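# Muller element -> linkage class per species.
# Element A is the ancestral X in every species.  Muller D is ancestrally
# autosomal but fused into a neo-X in the obscura clade (Dpse, Dper).
default:
  A: X-linked
  B: autosomal
  C: autosomal
  D: autosomal
  E: autosomal
  F: autosomal
overrides:
  Dpse:
    D: X-linked
  Dper:
    D: X-linked
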