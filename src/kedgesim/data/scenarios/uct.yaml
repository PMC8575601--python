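# Micro-CT exposure presets: preclinical scanner with 1 mm Al + 0.15 mm Be
# inherent filtration; vials sit inside a 3.9 cm PMMA cylindrical phantom.
name: uct
geometry: uct
inherent_filtration:
  - {material: Al, mm: 1.0}
  - {material: Be, mm: 0.15}
pmma_path_cm: 3.9
sample_path_cm: 1.0
scans:
  - {scan_id: X01, kvp: 50, cu_mm: 0.6, mAs: 10.0}
  - {scan_id: X02, kvp: 80, cu_mm: 0.6, mAs: 7.5}
  - {scan_id: X03, kvp: 120, cu_mm: 0.6, mAs: 2.5}
  - {scan_id: X04, kvp: 120, cu_mm: 1.2, mAs: 2.5}
  - {scan_id: X05, kvp: 120, cu_mm: 1.6, mAs: 5.0}
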