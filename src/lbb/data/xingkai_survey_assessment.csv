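species,year,b_over_b0,b_over_bmsy,f_over_m,z_over_k,yr_prime,e,linf_cm,lc_over_lcopt,lmean_over_lopt,l95_over_linf,stock_status
H. leucisculus,2019,0.22,0.59,2.87,6.03,0.041,0.73,19.9,1.20,1.20,0.93,overfished
H. leucisculus,2024,0.67,1.90,0.52,3.22,0.010,0.34,19.1,1.70,1.40,0.94,healthy
H. lucidus,2019,0.23,0.64,2.69,6.08,0.037,0.73,19.2,1.20,1.20,0.94,overfished
H. lucidus,2024,0.42,1.20,1.40,5.50,0.011,0.59,20.9,1.60,1.50,0.93,healthy
Ca. gibelio,2019,0.25,0.67,1.27,3.09,0.050,0.57,27.1,0.71,0.81,0.85,overfished
Ca. gibelio,2024,0.51,1.40,0.48,2.34,0.033,0.32,27.2,0.79,0.84,0.88,healthy
A. macropterus,2019,0.23,0.64,1.81,4.67,0.041,0.65,12.3,0.99,0.99,0.78,overfished
A. macropterus,2024,0.80,2.10,0.19,1.55,0.020,0.16,10.3,1.30,1.10,0.99,healthy
Cu. alburnus,2019,0.27,0.69,1.40,2.35,0.084,0.59,53.6,0.84,0.91,0.95,overfished
Cu. alburnus,2024,0.30,0.78,1.46,2.70,0.072,0.59,52.4,0.99,0.99,0.93,overfished
Ch. mongolicus,2019,0.06,0.17,4.44,8.74,0.009,0.82,41.4,0.64,0.73,0.77,collapsed
Ch. mongolicus,2024,0.14,0.40,1.98,4.75,0.022,0.66,42.7,0.62,0.73,0.82,grossly overfished
Ch. abramoides,2019,0.15,0.44,2.85,7.65,0.020,0.74,29.9,1.00,1.00,0.90,grossly overfished
Ch. abramoides,2024,0.17,0.46,2.06,5.07,0.027,0.68,32.9,0.79,0.85,0.94,grossly overfished
Ch. erythropterus,2019,0.09,0.26,2.76,5.90,0.014,0.75,34.6,0.60,0.70,0.82,grossly overfished
Ch. erythropterus,2024,0.14,0.39,1.99,4.46,0.023,0.67,35.8,0.62,0.73,0.85,grossly overfished
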