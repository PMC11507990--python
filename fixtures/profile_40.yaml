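name: '40'
horizon: 7
n_blocks: 3
block_capacity: 360.0
classes:
- id: 0
  mwt: 8
  count: 1
  tardy_count: 1
  mean_waited: 12.0
- id: 1
  mwt: 30
  count: 8
  tardy_count: 4
  mean_waited: 38.88
- id: 2
  mwt: 60
  count: 26
  tardy_count: 4
  mean_waited: 44.04
- id: 3
  mwt: 180
  count: 3
  tardy_count: 1
  mean_waited: 158.33
- id: 4
  mwt: 360
  count: 2
  tardy_count: 0
  mean_waited: 334.5
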