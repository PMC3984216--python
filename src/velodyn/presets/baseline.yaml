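# Business as usual: no investment in cycling infrastructure.
policy:
  scenario: baseline
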