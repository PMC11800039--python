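dt_fs: 1.0
forcefield: {}
gamma_per_ps: 4.0
max_fs_per_pair: 20000.0
outdir: scratch/readme_run
pair_target_A: 5.8
relaxation_gap_fs: 0.0
rise_A: 3.4
seed: 1
sequence: TTGCG
smooth_window_fs: 500.0
spring_stiffness_N_per_cm: 0.01
stage1_ps: 10.0
stage3_ps: 10.0
stride: 1
temperature_K: 300.0
threshold_A: 8.2
tip_speed_A_per_fs: 0.002
twist_deg: 36.0
xyz_stride: 50
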