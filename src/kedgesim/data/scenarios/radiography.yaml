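# Digital radiography presets on a clinical tube: 3.9 mm Al inherent
# filtration, 0-1.5 mm added Cu, wells 102 cm from the focal spot.
# The two 121 kVp exposures with little filtration saturate a real
# flat-panel detector and are flagged excluded from analysis.
name: radiography
geometry: radiography
inherent_filtration:
  - {material: Al, mm: 3.9}
source_distance_cm: 102
sample_path_cm: 0.2
scans:
  - {scan_id: X12, kvp: 50, cu_mm: 0.0, mA: 1.25}
  - {scan_id: X13, kvp: 50, cu_mm: 0.1, mA: 2.5}
  - {scan_id: X14, kvp: 50, cu_mm: 0.3, mA: 10.0}
  - {scan_id: X15, kvp: 50, cu_mm: 0.5, mA: 36.0}
  - {scan_id: X16, kvp: 50, cu_mm: 1.0, mA: 71.0}
  - {scan_id: X17, kvp: 50, cu_mm: 1.5, mA: 71.0}
  - {scan_id: X18, kvp: 81, cu_mm: 0.0, mA: 1.25}
  - {scan_id: X19, kvp: 81, cu_mm: 0.1, mA: 1.6}
  - {scan_id: X20, kvp: 81, cu_mm: 0.3, mA: 1.6}
  - {scan_id: X21, kvp: 81, cu_mm: 0.5, mA: 2.2}
  - {scan_id: X22, kvp: 81, cu_mm: 1.0, mA: 4.0}
  - {scan_id: X23, kvp: 81, cu_mm: 1.5, mA: 4.0}
  - {scan_id: X24, kvp: 121, cu_mm: 0.0, mA: 1.25, excluded: true}
  - {scan_id: X25, kvp: 121, cu_mm: 0.1, mA: 1.25, excluded: true}
  - {scan_id: X26, kvp: 121, cu_mm: 0.3, mA: 1.25}
  - {scan_id: X27, kvp: 121, cu_mm: 0.5, mA: 1.25}
  - {scan_id: X28, kvp: 121, cu_mm: 1.0, mA: 1.25}
  - {scan_id: X29, kvp: 121, cu_mm: 1.5, mA: 1.25}
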