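# Demo analysis configuration: a synthetic two-group resting-state cohort.
# Patients share the controls' background couplings and carry extra,
# stronger couplings -- the synthetic analogue of tinnitus hyper-connectivity.
out_dir: results/demo
seed: 11
fs: 600.0          # Hz
duration: 300.0    # 5-minute recordings
n_nodes: 20
n_per_group: 10
n_shared_edges: 8
n_patient_extra_edges: 5
shared_strength: [0.3, 0.5]
patient_strength: [0.55, 0.65]
delay_range: [10, 30]
highpass_hz: 0.5
notch_hz: 50.0
lowpass_hz: 35.0
n_epochs: 8
epoch_seconds: 8.0
exclude_seconds: 60.0
bin_mode: joint_adequate
# permutation p-values are bounded below by 1/(B+1); at q = 0.001 over 380
# edges, k rejections need B+1 >= 380/(k*0.001), hence the large count
n_permutations: 100000
fdr_q: 0.001
swp_n_null: 50
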