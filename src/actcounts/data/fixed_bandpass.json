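{
 "kind": "analog",
 "num": [
  14809.126110994874,
  0.0,
  0.0,
  0.0,
  0.0
 ],
 "den": [
  1.0,
  32.16647304334172,
  604.6988246395889,
  5999.740118896241,
  39538.63620162386,
  127591.3055167127,
  272391.4708189481,
  319027.10132696223,
  219892.87612950473
 ],
 "fs": null,
 "band": null
}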