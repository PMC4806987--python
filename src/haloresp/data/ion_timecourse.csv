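# haloresp ion time-course dataset fixture, version 1.0
# Built-in potassium-uptake / sodium-release time course with two
# steady-state scalars, used as the observation set for parameter fitting.
# steady_state_ATP_mmol_per_kg_cell_water: 3.7
# steady_state_pmf_mV: 280
# t_final_s: 3600
time_min,K_mmol_per_L,Na_mmol_per_L
0,2304.7,1851.6
4.8,2437.5,1695.3
10,2601.6,1718.8
20,2828.1,1492.2
40,2828.1,NA
60,2937.5,1296.9
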