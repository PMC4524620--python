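{
  "peaks": [
    {
      "height": 0.1925269478206895,
      "center_ppm": 3.961253,
      "fwhm_ppm": 0.6362,
      "phase_rad": 0.0
    },
    {
      "height": 0.31580176309849217,
      "center_ppm": -5.064015,
      "fwhm_ppm": 0.4249,
      "phase_rad": 0.0
    },
    {
      "height": 0.14370728153050014,
      "center_ppm": -5.503231,
      "fwhm_ppm": 0.8113,
      "phase_rad": 0.0
    },
    {
      "height": 0.18526023134308653,
      "center_ppm": 3.048056,
      "fwhm_ppm": 0.6403,
      "phase_rad": 0.0
    },
    {
      "height": 0.18661438291495144,
      "center_ppm": 1.778537,
      "fwhm_ppm": 0.7756,
      "phase_rad": 0.0
    }
  ],
  "fractional_areas": [
    0.19240000000000002,
    0.210776,
    0.18313869999999996,
    0.18633120000000006,
    0.22735409999999998
  ],
  "zero_order_phase_rad": 0.0,
  "dwell_s": 0.001,
  "effective_dwell_s": 4.063842533284889e-05,
  "acq_s": 0.12,
  "freq_mhz": 376.5,
  "noise_sigma": 0.0,
  "target_snr": 100.0,
  "seed": 7
}
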