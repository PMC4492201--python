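# cohort-csv v1
study_label,year,modality,dose_per_fraction,n_fractions,total_dose,dose_low,dose_high,fractions_per_week,overall_time_days,chemo_category,n_total,os1y_percent,os2y_percent,median_os_months,included_in_fit,exclusion_reason
Chung 2004,2004,xray,1.8,25,45,,,5,,gemcitabine_plus_other,22,50,,12,true,
Haddock 2007,2007,xray,1.8,25,45,,,5,,gemcitabine_plus_other,48,40,,10.2,true,
Hong 2008,2008,xray,1.8,25,45,,,5,,gemcitabine_plus_other,38,63.3,27.9,16.7,true,
Mamon 2011,2011,xray,1.8,28,50.4,,,5,,gemcitabine_plus_other,78,51,,12.2,true,
Crane 2011,2011,xray,1.8,28,50.4,,,5,,gemcitabine_plus_other,69,66,25,19.2,true,
Brunner 2011,2011,xray,1.8,31,55.8,,,5,,gemcitabine_plus_other,58,53,,12.7,true,
Ch'Ang 2011,2011,xray,1.8,28,50.4,,,5,,gemcitabine_plus_other,50,68,20.6,14.5,true,
Tozzi 2013,2013,xray,7.5,6,45,,,5,,gemcitabine_plus_other,30,47,,11,true,
Ke 2014,2014,xray,1.8,28,50.4,,,5,,gemcitabine_plus_other,32,75,34.4,15.2,true,
Wang 2015,2015,xray,2.0,23,46,,,5,,gemcitabine_plus_other,16,71.1,40.6,19.5,true,
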