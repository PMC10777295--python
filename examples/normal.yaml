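# Wild-type reference run over the 28 h determination window.
parameter_set: reference
scenario: normal
settings:
  t_end: 28.0        # hours; tau defaults to the reference PHYL delay
output_dir: out/normal
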