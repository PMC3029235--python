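[scenario]
name = "zymosan"
stimulus_scale = 0.75
contact_protrusion_scale = 0.5
attraction_on = false
tension_rest = 0.025
tension_plateau = 0.3
ramp_onset = 10.0
ramp_duration = 60.0
viscosity_ramp_factor = 5.0
t_end = 400.0
resolution = 1.25
seed = 0
cell_radius = 4.25
target_radius = 1.6
initial_contact_angle = 0.25
tau_transient = 10.0
annulus_segments = 2
cfl = 0.4
dt_max = 0.5
completion_margin = 20.0
activation_time = 5.0

[parameters]
mu_solvent = 10.0
mu_network_0 = 25000.0
bulk_ratio = 1.0
drag_coeff = 100000.0
k_poly = 0.7
k_depoly = 1.0
theta_base = 0.02
theta_max = 0.5
D_m = 1.0
k_decay = 2.0
source_strength = 2.0
sigma_protrude = 6000.0
sigma_attract = 1000.0
sigma_adhesion = 6000.0
capture_range = 0.65
stab_alpha = 0.2
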