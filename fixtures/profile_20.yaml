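name: '20'
horizon: 7
n_blocks: 2
block_capacity: 360.0
classes:
- id: 0
  mwt: 8
  count: 1
  tardy_count: 0
  mean_waited: 6.0
- id: 1
  mwt: 30
  count: 6
  tardy_count: 3
  mean_waited: 34.0
- id: 2
  mwt: 60
  count: 8
  tardy_count: 3
  mean_waited: 66.75
- id: 3
  mwt: 180
  count: 4
  tardy_count: 2
  mean_waited: 173.75
- id: 4
  mwt: 360
  count: 1
  tardy_count: 0
  mean_waited: 338.0
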