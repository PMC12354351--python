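# Default domain-knowledge tables.  These are data, not claims: override
# with a site-specific file for real deployments.
acute:
  - vomiting
  - tachycardia
chronic:
  - stomach ache
  - liver accumulation
  - cataract
tcm_diseases:
  - stomach ache
  - vomiting
  - liver accumulation
  - tachycardia
  - cataract
western_classes:
  gastritis: digestive
  hepatitis: digestive
  arrhythmia: circulatory
  cataract: eye
# stem -> five-element override table (empty: use the canonical pairing)
stem_elements: {}
# innate-constitution lookup keyed "<stem>-<birth month>"; entries override
# the built-in stem-element x seasonal-qi combination
constitution: {}
top_m: 3
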