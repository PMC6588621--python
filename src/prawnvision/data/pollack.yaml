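# Dichromatic pollack (Pollachius pollachius) visual system.
# Single cones peak at 436 nm; each double-cone member (521 nm) is treated as
# an independent channel. Cone abundance ratio 0.70:1 (shortest to longest);
# reference noise-to-signal ratio 0.05 for the most abundant cone class.
name: pollack
ocular_cutoff_nm: 410
nu: 0.05
channels:
  - name: SWS
    lambda_max_nm: 436
    relative_abundance: 0.70
  - name: LWS        # 521 nm double cone; the paper's "MWS", used as the
    lambda_max_nm: 521  # long channel of the dichromat hue ratio SWS/LWS
    relative_abundance: 1.0
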