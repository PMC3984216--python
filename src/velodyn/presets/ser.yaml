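# Self-explaining roads: low-speed bicycle-friendly redesign of local
# streets (up to 15 km/h mean-speed reduction, 25% local volume reduction,
# cycling shifted toward local streets, light-vehicle convenience down 30%).
# Complete by 2050.
policy:
  scenario: ser
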