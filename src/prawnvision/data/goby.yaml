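# Trichromatic two-spotted goby (Gobiusculus flavescens) visual system.
# Single cones at 456 nm (SWS), double-cone members at 531 nm (MWS) and
# 553 nm (LWS), each treated as an independent channel. Cone abundance
# ratios 0.72:1:0.60 (shortest to longest); reference noise-to-signal
# ratio 0.05 for the most abundant class.
name: goby
ocular_cutoff_nm: 410
nu: 0.05
channels:
  - name: SWS
    lambda_max_nm: 456
    relative_abundance: 0.72
  - name: MWS
    lambda_max_nm: 531
    relative_abundance: 1.0
  - name: LWS
    lambda_max_nm: 553
    relative_abundance: 0.60
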