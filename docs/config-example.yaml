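# Example opusdmi configuration (all sections and fields optional; omitted
# fields take the package defaults, which reproduce the full-size probe:
# 64 sources over 15 mm, 62.5 MSa/s x 1004 samples, 10 x 7 mm image at
# 50 x 25 um pixels).
#
# Keys may carry a unit suffix (_m, _mm, _um, _s, _us, _ns, _hz, _khz,
# _mhz); unsuffixed keys are SI (metres, seconds, Hz).

probe:
  n_sources: 64
  aperture_width_mm: 15
  source_radius_um: 100          # 200 um fibre core diameter
  jitter_fraction: 0.0           # lateral jitter in fractions of the pitch
  seed: 20241121
  # alternatively, give explicit positions (metres, z = 0 plane):
  # source_centers: [[-0.0075, 0.0, 0.0], ...]
  # receiver_position: [0.0, 0.0, 0.0]

acquisition:
  sampling_rate_mhz: 62.5
  n_time_samples: 1004
  sound_speed: 1500              # m/s
  time_origin_us: 0              # first stored sample re excitation

grid:
  x_extent_mm: [-5, 5]           # pixel centres inclusive of both ends
  z_extent_mm: [0, 7]
  dx_um: 50
  dz_um: 25

inversion:
  sv_threshold: 1.0e-4           # on singular values normalised by max(S)
  regularizer: tikhonov          # tikhonov | tsvd
  alpha: 0.01
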