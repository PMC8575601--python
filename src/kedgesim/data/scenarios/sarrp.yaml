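# Planar imaging presets on the small-animal radiation research platform:
# 120-220 kVp in 20 kVp steps, 0.1 mm Cu added filtration, cuvettes 30 cm
# from the tube.
name: sarrp
geometry: sarrp
inherent_filtration:
  - {material: Al, mm: 1.0}
  - {material: Be, mm: 0.15}
source_distance_cm: 30
sample_path_cm: 1.0
scans:
  - {scan_id: X06, kvp: 120, cu_mm: 0.1, mA: 0.5}
  - {scan_id: X07, kvp: 140, cu_mm: 0.1, mA: 0.5}
  - {scan_id: X08, kvp: 160, cu_mm: 0.1, mA: 0.5}
  - {scan_id: X09, kvp: 180, cu_mm: 0.1, mA: 0.5}
  - {scan_id: X10, kvp: 200, cu_mm: 0.1, mA: 0.5}
  - {scan_id: X11, kvp: 220, cu_mm: 0.1, mA: 0.5}
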