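# Cellular Potts tissue model configuration

size = 200
lumen_radius = 45.0
epidermis_inner_radius = 78.0
epidermis_thickness = 4.0
n_epidermal_cells = 48
n_fibroblasts = 10
fibroblast_spoke_halfangle = 0.03
temperature = 14.0
lambda_volume = 4.0
ecm_stiffness = 25.0
target_volume = 25.0
division_volume = 45.0
target_volume_cap = 60.0
qf_target_volume = 12.0
target_relax = 0.02
qf_condense_rate = 0.01
j_cell_medium = 9.0
j_cell_cell = 20.0
j_cell_ecm = 4.0
j_cell_epidermis = 25.0
j_cell_clot = 8.0
j_epidermis_medium = 6.0
j_epidermis_epidermis = 2.0
j_epidermis_clot = 6.0
j_default = 10.0
epi_amplitude = 1.0
epi_half_life_mcs = 90.0
epi_decay = 0.003
epi_sweeps = 6
wound_amplitude = 1.0
wound_half_life_mcs = 150.0
wound_decay = 0.08
wound_sweeps = 6
growth_rate = 2.5
wound_growth_rate = 2.5
epidermal_wound_growth = 0.3
p_deposit_qf = 0.055
p_deposit_pf = 0.005
p_ecm_spread = 0.009
p_ecm_compact = 0.02
adipocyte_onset_mcs = 300
wound_mcs = 1200
end_mcs = 1500
wound_halfangle = 0.13
activation_radius = 14.0
n_immune_cells = 6
chemotaxis_activated = 60.0
chemotaxis_epidermis = 30.0
seed = 0
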