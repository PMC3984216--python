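# Regional cycle network: painted on-road lanes on 46% of arterial roads,
# off-road shared paths growing from 10 to 25 km per 100,000 population,
# and a negligible quantity of shared bus/bicycle lanes. Complete by 2040.
policy:
  scenario: rcn
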