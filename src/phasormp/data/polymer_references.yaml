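# SYNTHETIC STAND-IN emission models -- not measured values.
# Peak positions/widths are invented to be qualitatively consistent with
# solvatochromic staining of these polymers (polyolefins: two peaks in
# 450-520 nm; PS/PET: single broader peak above 520 nm, PET reddest and
# broadest). Edit freely to substitute measured spectra.
- name: PP
  peaks:
    - {center: 455.0, sigma: 12.0, amplitude: 1.0}
    - {center: 485.0, sigma: 13.0, amplitude: 0.85}
  dielectric_range: [2.2, 2.5]
  display_color: [0.0, 0.3, 1.0]
  synthetic_standin: true
- name: LDPE
  peaks:
    - {center: 468.0, sigma: 12.0, amplitude: 1.0}
    - {center: 500.0, sigma: 13.0, amplitude: 0.82}
  dielectric_range: [2.2, 2.35]
  display_color: [0.0, 0.8, 0.4]
  synthetic_standin: true
- name: HDPE
  peaks:
    - {center: 474.0, sigma: 12.0, amplitude: 1.0}
    - {center: 506.0, sigma: 13.0, amplitude: 0.82}
  dielectric_range: [2.3, 2.4]
  display_color: [0.0, 0.6, 0.2]
  synthetic_standin: true
- name: PS
  peaks:
    - {center: 545.0, sigma: 35.0, amplitude: 1.0}
  dielectric_range: [2.4, 3.1]
  display_color: [1.0, 0.9, 0.0]
  synthetic_standin: true
- name: PET
  peaks:
    - {center: 600.0, sigma: 55.0, amplitude: 1.0}
  dielectric_range: [3.0, 4.0]
  display_color: [1.0, 0.1, 0.1]
  synthetic_standin: true
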