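# Default generator calibration, version 1.
#
# Archetype envelope levels are per-subphase means (SD) in percent-of-mean
# EMG units for the gluteus medius over one gait cycle; clinical scalars are
# hip abduction passive RoM (degrees, at 90 and 0 degrees hip flexion) and
# hip abductor strength (MRC grade 0-5).  Outcome groups give pre/post
# (E1/E2) frontal-plane gait parameters and swing-window EMG summaries for
# the responder (SUB_1) / non-responder (SUB_2) structure.
version: 1

archetypes:
  cluster_1:
    phase_mean: {LR: 170.1, MSt: 126.9, TSt: 85.8, PSw: 81.3, ISw: 72.4, MSw: 64.5, TSw: 90.8}
    phase_sd:   {LR: 40.2,  MSt: 24.7,  TSt: 15.8, PSw: 22.1, ISw: 19.1, MSw: 19.4, TSw: 28.1}
    clin_mean: {rom_hip_abd_90: 32.8, rom_hip_abd_0: 35.1, strength_90: 4.0, strength_0: 3.6}
    clin_sd:   {rom_hip_abd_90: 12.8, rom_hip_abd_0: 8.6,  strength_90: 0.9, strength_0: 0.8}
  cluster_2:
    phase_mean: {LR: 230.2, MSt: 145.1, TSt: 79.52, PSw: 56.1, ISw: 46.6, MSw: 42.4, TSw: 104.5}
    phase_sd:   {LR: 59.4,  MSt: 32.9,  TSt: 24.1,  PSw: 27.4, ISw: 21.3, MSw: 20.4, TSw: 35.2}
    clin_mean: {rom_hip_abd_90: 35.1, rom_hip_abd_0: 37.2, strength_90: 4.1, strength_0: 3.8}
    clin_sd:   {rom_hip_abd_90: 12.6, rom_hip_abd_0: 10.0, strength_90: 0.8, strength_0: 0.7}
  cluster_3:
    phase_mean: {LR: 273.6, MSt: 135.6, TSt: 64.5, PSw: 60.5, ISw: 49.6, MSw: 41.9, TSw: 108.1}
    phase_sd:   {LR: 61.5,  MSt: 31.8,  TSt: 20.8, PSw: 33.2, ISw: 23.3, MSw: 18.4, TSw: 41.7}
    clin_mean: {rom_hip_abd_90: 41.5, rom_hip_abd_0: 42.1, strength_90: 4.5, strength_0: 4.0}
    clin_sd:   {rom_hip_abd_90: 13.4, rom_hip_abd_0: 9.9,  strength_90: 0.7, strength_0: 0.7}
  TD:
    phase_mean: {LR: 264.9, MSt: 113.3, TSt: 71.1, PSw: 68.4, ISw: 60.1, MSw: 57.2, TSw: 95.4}
    phase_sd:   {LR: 91.3,  MSt: 36.1,  TSt: 29.1, PSw: 38.1, ISw: 28.5, MSw: 26.7, TSw: 30.4}
    clin_mean: {rom_hip_abd_90: 50.4, rom_hip_abd_0: 49.1, strength_90: 5.0, strength_0: 5.0}
    clin_sd:   {rom_hip_abd_90: 10.5, rom_hip_abd_0: 6.9,  strength_90: 0.0, strength_0: 0.0}

# E2 swing-window EMG for SUB_1 is not tabulated by the calibration source;
# the responder group's post-treatment levels are set to the non-responder
# pre-treatment profile (prolonged swing activity resolved), SDs kept from
# its own E1.  SUB_2 is modelled as unchanged between examinations.
outcomes:
  SUB_1:
    e1_mean: {rom_trunk_obl: 15.4, rom_pelvic_obl: 10.1, max_hip_abd_mst: 5.8, max_hip_abd_moment_mst: 0.46}
    e1_sd:   {rom_trunk_obl: 7.4,  rom_pelvic_obl: 3.5,  max_hip_abd_mst: 3.9, max_hip_abd_moment_mst: 0.25}
    e2_mean: {rom_trunk_obl: 10.5, rom_pelvic_obl: 11.9, max_hip_abd_mst: 6.5, max_hip_abd_moment_mst: 0.52}
    e2_sd:   {rom_trunk_obl: 5.4,  rom_pelvic_obl: 4.7,  max_hip_abd_mst: 3.5, max_hip_abd_moment_mst: 0.22}
    emg_e1_mean: {emg_mean: 79.5, emg_min: 50.7, emg_max: 111.7}
    emg_e1_sd:   {emg_mean: 19.2, emg_min: 15.1, emg_max: 31.9}
    emg_e2_mean: {emg_mean: 68.6, emg_min: 45.5, emg_max: 99.1}
    emg_e2_sd:   {emg_mean: 19.2, emg_min: 15.1, emg_max: 31.9}
    exam_mean: {rom_hip_abd_90: 37.2, rom_hip_abd_0: 35.8, strength_90: 3.9, strength_0: 3.5}
    exam_sd:   {rom_hip_abd_90: 12.5, rom_hip_abd_0: 7.9,  strength_90: 0.5, strength_0: 0.5}
  SUB_2:
    e1_mean: {rom_trunk_obl: 11.5, rom_pelvic_obl: 9.5, max_hip_abd_mst: 6.0, max_hip_abd_moment_mst: 0.52}
    e1_sd:   {rom_trunk_obl: 4.4,  rom_pelvic_obl: 4.6, max_hip_abd_mst: 3.9, max_hip_abd_moment_mst: 0.18}
    e2_mean: {rom_trunk_obl: 10.8, rom_pelvic_obl: 8.9, max_hip_abd_mst: 5.3, max_hip_abd_moment_mst: 0.55}
    e2_sd:   {rom_trunk_obl: 5.8,  rom_pelvic_obl: 4.7, max_hip_abd_mst: 4.3, max_hip_abd_moment_mst: 0.14}
    emg_e1_mean: {emg_mean: 68.6, emg_min: 45.5, emg_max: 99.1}
    emg_e1_sd:   {emg_mean: 8.7,  emg_min: 10.8, emg_max: 21.9}
    emg_e2_mean: {emg_mean: 68.6, emg_min: 45.5, emg_max: 99.1}
    emg_e2_sd:   {emg_mean: 8.7,  emg_min: 10.8, emg_max: 21.9}
    exam_mean: {rom_hip_abd_90: 29.6, rom_hip_abd_0: 32.7, strength_90: 4.0, strength_0: 3.4}
    exam_sd:   {rom_hip_abd_90: 10.3, rom_hip_abd_0: 7.1,  strength_90: 1.0, strength_0: 0.6}
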