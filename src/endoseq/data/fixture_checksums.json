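{
 "clinical_pediatric_cohort1.tsv": "a41d296e4edff09618eebd409fae518946df79671fb9354baf61eefce4201e57",
 "clinical_adult.tsv": "d7772c78497ec6b001b2b23a1c3410d295f53cf00c644c0320f27e53061eefab"
}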