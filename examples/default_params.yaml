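n_units: 180
theta: 25.0
slope: 0.3
tau_unit: 3.0
tau_a: 15.0
tau_v: 25.0
tau_in: 180.0
tau_c: 3.0
tau_c_off: 80.0
tau_iex: 15.0
tau_q_off: 1750.0
tau_iin: 15.0
tau_m: 15.0
delta_t_cross: 16.0
delta_t_m: 50.0
delta_t_pm: 50.0
sigma_a: 50.0
sigma_v: 4.0
i0_a: 55.0
i0_v: 55.0
jitter_rel: 0.3
stim_duration_ms: 60.0
av_ratio: 0.95
wma0: 0.12
wm_sd: 5.0
wva0: 0.12
wva_sd: 5.0
wav_sd: 7.0
wia0: 0.2
wi_sd: 5.0
laiv0: 0.0057
lvia0: 0.016
fb_sd: 15.0
wta0: 10.0
wpmm0: 1.0
la_ex0: 5.0
la_ex_sd: 3.0
la_in0: 4.0
la_in_sd: 120.0
lv_ex0: 5.0
lv_ex_sd: 3.0
lv_in0: 4.0
lv_in_sd: 120.0
lm_ex0: 0.4
lm_ex_sd: 4.0
lm_in0: 0.3
lm_in_sd: 8.0
gain_a: 1.0
gain_v: 1.0
gain_cross_a: 20.0
gain_cross_v: 23.0
gain_inh_a: 26.0
gain_inh_v: 40.0
gain_ie: 60.0
gain_wta: 3.0
gain_m: 95.0
gain_m_lat: 10.0
gain_pm: 38.0
rt_threshold: 0.3
anticipatory_cutoff_ms: 100.0
response_window_ms: 1000.0
dt_ms: 0.1
rng_seed: 0
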