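# Monte Carlo dose-study presets: water-equivalent 30 x 30 x 20 cm cuboid,
# source 100 cm away, 20 cm diameter field at the entry face, transmitted
# count equalized to 8.5e5 photons.  incident_mean_energy_keV records a
# measured mean energy for the beam entering the phantom; the matched
# spectrum mode conditions the analytic spectra on these values.
name: dose
geometry: dose-phantom
inherent_filtration:
  - {material: Al, mm: 1.0}
  - {material: Be, mm: 0.15}
source_distance_cm: 100
target_transmitted: 8.5e5
reference_scan_id: D120-05
scans:
  - {scan_id: D050-00, kvp: 50, cu_mm: 0.0, incident_mean_energy_keV: 31.8}
  - {scan_id: D080-00, kvp: 80, cu_mm: 0.0, incident_mean_energy_keV: 42.4}
  - {scan_id: D120-00, kvp: 120, cu_mm: 0.0, incident_mean_energy_keV: 53.7}
  - {scan_id: D120-01, kvp: 120, cu_mm: 0.1, incident_mean_energy_keV: 59.0}
  - {scan_id: D120-03, kvp: 120, cu_mm: 0.3, incident_mean_energy_keV: 64.9}
  - {scan_id: D120-05, kvp: 120, cu_mm: 0.5, incident_mean_energy_keV: 68.1}
  - {scan_id: D120-10, kvp: 120, cu_mm: 1.0, incident_mean_energy_keV: 74.1}
  - {scan_id: D120-15, kvp: 120, cu_mm: 1.5, incident_mean_energy_keV: 78.4}
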