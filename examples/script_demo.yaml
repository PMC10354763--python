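# Merge the particle-bearing droplet into d2, mix, park at the SET, extract.
operations:
  - op: merge
    moving: d1
    still: d2
  - op: mix
    loops: 2
    arm_length: 25
  - op: transport
    droplet: d1
    destinations: [[320, 200]]
  - op: extract
    direction: EAST
    travel: 60
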