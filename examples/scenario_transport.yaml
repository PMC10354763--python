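# Demo scenario: 10 μl droplets; 1 μl of particles (extraction-friendly —
# a 0.5 μl cluster would disengage at the high extraction speeds).
bounds: [40, 40]
model:
  k_mag: 20
  k_exit: 8
  k_drag: 12
  set_factor: 0.5
  power_gain: 1.5
magnet:
  position: [2, 2]
  power: default
  lag: 0
droplets:
  - {id: d1, center: [10, 20], volume: 10, particle_volume: 1.0}
  - {id: d2, center: [25, 20], volume: 10}
sets:
  - {id: s1, center: [32, 20], radius: 1.5}
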