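{
  "Pixel 4": -22.5,
  "Pixel 7": -14.0,
  "Galaxy S22": -19.6,
  "Moto G 2022": -14.9
}
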