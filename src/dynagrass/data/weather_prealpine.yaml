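# Synthetic generator targets for a high-elevation pre-alpine valley site
# (~860 m a.s.l.).  Monthly normals chosen so the March-October means come
# out near 10.8 degC and 1219 mm, realistic for intensively cut grassland
# in the northern Alpine foothills.  Calibration fixture of this package.
tmin_mean: [-8.0, -7.0, -3.0, 1.0, 6.5, 9.5, 11.5, 11.0, 7.0, 3.0, -3.0, -7.0]
tmax_mean: [2.0, 3.0, 7.0, 11.0, 16.5, 19.5, 21.5, 21.0, 17.0, 13.0, 7.0, 3.0]
tmin_sd: [3.5, 3.5, 3.0, 3.0, 2.5, 2.5, 2.5, 2.5, 2.5, 3.0, 3.0, 3.5]
tmax_sd: [3.5, 3.5, 3.0, 3.0, 2.5, 2.5, 2.5, 2.5, 2.5, 3.0, 3.0, 3.5]
p_wet: [0.45, 0.45, 0.50, 0.50, 0.50, 0.50, 0.50, 0.50, 0.50, 0.45, 0.45, 0.45]
p_wet_wet: [0.65, 0.65, 0.65, 0.65, 0.65, 0.65, 0.65, 0.65, 0.65, 0.65, 0.65, 0.65]
precip_wet_mean: [5.4, 5.6, 7.1, 8.0, 10.3, 12.3, 12.3, 11.9, 9.7, 8.9, 6.7, 5.7]
rad_mean_dry: [50, 85, 130, 185, 225, 245, 235, 200, 155, 100, 60, 45]
rad_sd_dry: [20, 25, 35, 45, 50, 50, 50, 45, 40, 30, 20, 15]
rad_mean_wet: [30, 51, 78, 111, 135, 147, 141, 120, 93, 60, 36, 27]
rad_sd_wet: [12, 15, 20, 28, 32, 32, 32, 28, 25, 18, 12, 10]
precip_shape: 0.75
temp_autocorr: 0.7
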