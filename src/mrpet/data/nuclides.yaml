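# Nuclide registry: name -> physical half-life in minutes.
C-11: 20.364
N-13: 9.965
O-15: 2.037
F-18: 109.771
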