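# cohort-csv v1
study_label,year,modality,dose_per_fraction,n_fractions,total_dose,dose_low,dose_high,fractions_per_week,overall_time_days,chemo_category,n_total,os1y_percent,os2y_percent,median_os_months,included_in_fit,exclusion_reason
Terashima 2012,2012,proton,2.7,25,67.5,,,5,,gemcitabine,50,76.8,50,,true,
Sachsman 2014,2014,proton,1.8,33,59.4,,,5,,other,11,61,31,18.4,true,
"Yamada 2014 (40.8 Gy(RBE), no chemo)",2014,carbon,3.4,12,40.8,38.4,43.2,,21,none,19,36,5,,false,carbon-ion monotherapy arm; plotted but not part of the charged-particle chemoradiation fit
Yamada 2014 (40.8 Gy(RBE) + gemcitabine),2014,carbon,3.4,12,40.8,38.4,43.2,,21,gemcitabine,24,71,21,,true,
"Yamada 2014 (49.2 Gy(RBE), no chemo)",2014,carbon,4.1,12,49.2,45.6,52.8,,21,none,27,47,16,,false,carbon-ion monotherapy arm; plotted but not part of the charged-particle chemoradiation fit
Yamada 2014 (49.2 Gy(RBE) + gemcitabine),2014,carbon,4.1,12,49.2,45.6,52.8,,21,gemcitabine,47,74,54,,true,
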