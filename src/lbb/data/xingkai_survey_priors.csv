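species,year,min_cm,max_cm,class_interval_cm,numbers,linf_prior_cm,zk_prior,mk_prior,fk_prior,lc_prior_cm,alpha_prior
H. leucisculus,2019,5.5,18.5,0.5,396,19.5,2.4,1.5,0.94,10.7,12.5
H. leucisculus,2024,5.5,18.0,0.5,444,18.4,1.9,1.5,0.36,11.0,14.7
H. lucidus,2019,5.5,18.5,0.5,631,18.5,3.1,1.5,1.56,11.2,16.4
H. lucidus,2024,6.5,20.0,0.5,439,20.0,2.3,1.5,0.75,15.0,35.3
Ca. gibelio,2019,5.0,27.0,1.0,292,27.0,2.4,1.5,0.87,11.2,17.9
Ca. gibelio,2024,5.0,27.0,1.0,251,27.0,1.7,1.5,0.16,10.7,21.0
A. macropterus,2019,4.2,10.2,0.3,169,12.2,3.0,1.5,1.46,6.9,48.0
A. macropterus,2024,5.4,11.7,0.3,347,11.7,2.5,1.5,0.96,6.9,39.7
Cu. alburnus,2019,8.0,51.0,2.0,266,51.6,1.7,1.5,0.22,22.4,8.4
Cu. alburnus,2024,8.0,51.0,2.0,192,50.9,2.7,1.5,1.19,25.5,8.9
Ch. mongolicus,2019,8.0,35.0,1.0,342,41.2,5.9,1.5,4.43,15.8,46.4
Ch. mongolicus,2024,8.0,35.0,1.0,349,41.0,4.7,1.5,3.24,15.8,35.5
Ch. abramoides,2019,6.0,29.0,1.0,342,29.0,4.1,1.5,2.55,12.8,17.8
Ch. abramoides,2024,6.0,31.0,1.0,343,31.7,4.3,1.5,2.79,12.8,20.4
Ch. erythropterus,2019,5.5,29.5,1.0,267,33.9,5.0,1.5,3.54,11.7,38.1
Ch. erythropterus,2024,4.5,30.5,1.0,415,34.9,4.7,1.5,3.19,12.8,23.2
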