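# Arterial segregated bicycle lanes with intersection treatments on the
# whole arterial network (collision RR 0.72 midblock / 0.80 intersection).
# Complete by 2050.
policy:
  scenario: asbl
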