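# Combined best practice: arterial segregated lanes plus self-explaining
# local streets; the effects compose at every rollout fraction.
policy:
  scenario: asbl_ser
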