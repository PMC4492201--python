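# cohort-csv v1
study_label,year,modality,dose_per_fraction,n_fractions,total_dose,dose_low,dose_high,fractions_per_week,overall_time_days,chemo_category,n_total,os1y_percent,os2y_percent,median_os_months,included_in_fit,exclusion_reason
Moertel 1969,1969,xray,1.875,20,37.5,35,40,5,,none,28,7,,,true,
Moertel 1981,1981,xray,2.0,30,60,,,5,,none,25,10,,5.3,true,
Ceha 2000,2000,xray,1.9722,36,71,70,72,5,,none,44,39,,10,true,
Cohen 2005,2005,xray,1.8,33,59.4,,,5,,none,49,20,,7.1,true,
Wang 2015,2015,xray,2.0,23,46,,,5,,none,14,35,14,7.4,true,
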