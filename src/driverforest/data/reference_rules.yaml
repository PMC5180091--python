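# Ordered admission rules reconstructing the published high-confidence
# driver-gene curation from multi-study evidence sources, plus the tier
# configuration for the medium / low confidence exclusion sets.
# Rules are applied in order; earlier rules take precedence.
rules:
  - name: base_curated_mutation
    type: base
    sources: [vogelstein_mutation]
  - name: base_curated_cna
    type: base
    sources: [vogelstein_cna]
  - name: deletion_tsg_consensus
    type: and_k_of_m
    sources: [cgc, tag_db, tsgene, twenty_twenty]
    min_count: 2
    role: TSG
    mode: cna
  - name: curated_deletion_list
    type: base
    sources: [zack_deletion]
    role: TSG
    mode: cna
  - name: curated_amplification_list
    type: base
    sources: [zack_amplification]
    role: OG
    mode: cna
  - name: cgc_santarius_intersection
    type: intersection
    sources: [cgc, santarius]
    role: OG
    mode: cna
  - name: vote_5_of_7_mutation_methods
    type: vote
    sources: [lawrence, hotnet2, music, oncodriveclust, oncodrivefm,
              activedriver, twenty_twenty]
    min_count: 5
    roles: {CDK12: TSG, CTCF: TSG}
    mode: mutation
  - name: vote_4_of_7_mutation_methods
    type: vote
    sources: [lawrence, hotnet2, music, oncodriveclust, oncodrivefm,
              activedriver, twenty_twenty]
    min_count: 4
    roles: {ELF3: TSG, ZFHX3: TSG, RAC1: OG, TBX3: OG}
    mode: mutation

# MYCN is admitted as an amplified OG by the base CNA list and re-surfaces as
# a TSG on the curated deletion list; the literature supports both roles, so
# it is removed from the high-confidence set entirely.
overrides:
  MYCN: remove

tiers:
  medium_sources: [zack_deletion, zack_amplification, cgc, santarius,
                   lawrence, hotnet2, music, oncodriveclust, oncodrivefm,
                   activedriver]
  low_sources: [tag_db, tsgene, twenty_twenty, biomarker_high]
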