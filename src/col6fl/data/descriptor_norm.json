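{
 "reference_seed": 20240401,
 "n_reference_images": 80,
 "names": [
  "hist_r_0",
  "hist_r_1",
  "hist_r_2",
  "hist_r_3",
  "hist_r_4",
  "hist_r_5",
  "hist_r_6",
  "hist_r_7",
  "hist_r_8",
  "hist_r_9",
  "hist_r_10",
  "hist_r_11",
  "hist_r_12",
  "hist_r_13",
  "hist_r_14",
  "hist_r_15",
  "hist_g_0",
  "hist_g_1",
  "hist_g_2",
  "hist_g_3",
  "hist_g_4",
  "hist_g_5",
  "hist_g_6",
  "hist_g_7",
  "hist_g_8",
  "hist_g_9",
  "hist_g_10",
  "hist_g_11",
  "hist_g_12",
  "hist_g_13",
  "hist_g_14",
  "hist_g_15",
  "hist_b_0",
  "hist_b_1",
  "hist_b_2",
  "hist_b_3",
  "hist_b_4",
  "hist_b_5",
  "hist_b_6",
  "hist_b_7",
  "hist_b_8",
  "hist_b_9",
  "hist_b_10",
  "hist_b_11",
  "hist_b_12",
  "hist_b_13",
  "hist_b_14",
  "hist_b_15",
  "grad_s1_mean",
  "grad_s1_std",
  "grad_s1_p90",
  "grad_s2_mean",
  "grad_s2_std",
  "grad_s2_p90",
  "grad_s4_mean",
  "grad_s4_std",
  "grad_s4_p90",
  "orient_bin0",
  "orient_bin1",
  "orient_bin2",
  "orient_bin3",
  "orient_bin4",
  "orient_bin5",
  "orient_bin6",
  "orient_bin7",
  "orient_coherence",
  "blob_mean",
  "blob_p99",
  "blob_area",
  "band_ratio_fine",
  "band_ratio_coarse",
  "int_mean",
  "int_std",
  "int_m3"
 ],
 "center": [
  0.087828,
  0.489791,
  0.052312,
  0.075798,
  0.285113,
  0.364862,
  0.169119,
  0.029697,
  0.002033,
  4.9e-05,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.082356,
  0.439606,
  0.126121,
  0.179853,
  0.34,
  0.372536,
  0.225778,
  0.176795,
  0.153763,
  0.109367,
  0.074822,
  0.055748,
  0.039809,
  0.027549,
  0.018622,
  0.016508,
  0.089058,
  0.491525,
  0.025896,
  0.077493,
  0.293518,
  0.364705,
  0.155297,
  0.021915,
  0.000549,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.241627,
  0.229643,
  0.236896,
  0.241623,
  0.266282,
  0.278351,
  0.255869,
  0.249709,
  0.362317,
  0.468225,
  0.876135,
  1.191227,
  0.526044,
  0.290299,
  0.251264,
  0.269231,
  0.044685
 ],
 "scale": [
  0.0881,
  0.489695,
  0.046451,
  0.074798,
  0.285554,
  0.364886,
  0.170362,
  0.031269,
  0.003098,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  0.082871,
  0.440529,
  0.120949,
  0.064029,
  0.144131,
  0.235708,
  0.148962,
  0.12529,
  0.119351,
  0.093282,
  0.068793,
  0.053515,
  0.039923,
  0.029905,
  0.021971,
  0.020657,
  0.089278,
  0.491526,
  0.017507,
  0.077733,
  0.293728,
  0.36473,
  0.155906,
  0.022465,
  0.001476,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  0.090769,
  0.048463,
  0.137872,
  0.046614,
  0.024969,
  0.077277,
  0.018753,
  0.010356,
  0.032935,
  0.151052,
  0.129629,
  0.151549,
  0.126539,
  0.14701,
  0.162035,
  0.138736,
  0.140198,
  0.137,
  0.164034,
  0.183192,
  0.561981,
  0.063898,
  0.03687,
  0.13884,
  0.077849,
  0.023591
 ]
}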