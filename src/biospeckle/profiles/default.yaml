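distances:
- 1
- 2
- 3
- 4
- 5
- 6
- 7
- 8
- 9
- 10
directions:
- 0
- 45
- 90
- 135
levels: 256
symmetric: true
parameters:
- ASM
- CON
- IDM
- ENT
- DA
- DV
- DE
- CORR
reciprocal_blocks:
- ASM
- IDM
- CORR
selection_threshold: 0.8
selection_mode: explicit
explicit_drop_blocks:
- CORR
log_base: null
seed: 0
ra_list: []
roi: null
images_dir: null
out_dir: .
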