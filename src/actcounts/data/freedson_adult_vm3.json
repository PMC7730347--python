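{
 "name": "Freedson Adult VM3",
 "categories": [
  {"name": "Light", "lower": 0},
  {"name": "Moderate", "lower": 2960},
  {"name": "Vigorous", "lower": 6167},
  {"name": "Very vigorous", "lower": 9643}
 ]
}
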