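{
 "M": [
  [
   0.6491828991184352,
   0.15661181655609102
  ],
  [
   0.7036680218633762,
   0.9778025443222265
  ],
  [
   0.28881287800073374,
   0.13919383331161544
  ]
 ],
 "maxC": [
  1.3294009107892188,
  0.7705505766588079
 ],
 "alpha": 1.0,
 "beta": 0.15,
 "I0": 255.0
}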