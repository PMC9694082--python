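{
 "comment": "synthetic fixture: roles are 1-based alignment columns; loops are closed intervals",
 "roles": {
  "ring_DI": 16,
  "ring_DII": 18,
  "dII_plus1": 19,
  "ring_DIII": 21,
  "ring_DIV": 23,
  "turret_exon12": 8
 },
 "loops": {
  "L5_II": [
   1,
   14
  ],
  "L6_IV": [
   25,
   30
  ]
 },
 "per_record": {}
}
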