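# Operational cluster bounds (1-based, inclusive, intron-relative).
# The source report gives the PBX1 cluster bounds only approximately
# ("~220 to 229 kb", "~120 to ~155 kb"); these bounds are the operational
# choice that reproduces every printed membership count. They are
# configuration, not code.
tcf3:
  window_width: 40
pbx1:
  regions:
    - {start: 220000, end: 229182, label: cluster1}
    - {start: 119000, end: 155100, label: cluster2}
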