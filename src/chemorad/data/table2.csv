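# cohort-csv v1
study_label,year,modality,dose_per_fraction,n_fractions,total_dose,dose_low,dose_high,fractions_per_week,overall_time_days,chemo_category,n_total,os1y_percent,os2y_percent,median_os_months,included_in_fit,exclusion_reason
Wolff 2001,2001,xray,3.0,10,30,,,5,,gemcitabine,18,66,,6,true,
Epelbaum 2002,2002,xray,1.8,28,50.4,,,5,,gemcitabine,20,30,,,true,
Joensuu 2004,2004,xray,1.8,28,50.4,,,5,,gemcitabine,28,55,,25,true,
Okusaka 2004,2004,xray,1.8,28,50.4,,,5,,gemcitabine,38,28,23,9.5,true,
Murphy 2007,2007,xray,2.4,15,36,,,5,,gemcitabine,74,46,13,11.2,true,
Small 2008,2008,xray,2.4,15,36,,,5,,gemcitabine,14,47,,,true,
Igarashi 2008,2008,xray,1.8833,24,45.2,40,50.4,5,,gemcitabine,15,60,,15,true,
Schnellenberg 2008,2008,xray,25,1,25,,,5,,gemcitabine,16,50,,11.4,true,
Polistina 2010,2010,xray,10,3,30,,,5,,gemcitabine,23,39.1,0,10.6,true,
Loehrer 2011,2011,xray,1.8,28,50.4,,,5,,gemcitabine,34,50,12,11.1,true,
Schnellenberg 2011,2011,xray,25,1,25,,,5,,gemcitabine,20,50,20,11.8,true,
Cardenes 2011,2011,xray,1.8,28,50.4,,,5,,gemcitabine,28,30,11,10.3,true,
Shibuya 2011,2011,xray,1.8,30,54,,,5,,gemcitabine,21,74,,16.6,true,
Mahadevan 2011,2011,xray,10,3,30,24,36,5,,gemcitabine,39,72,33,20,true,
Huang 2011,2011,xray,1.7719,32,56.7,50.4,63,5,,gemcitabine,55,51,,12.5,true,
Mukherjee 2013,2013,xray,1.8,28,50.4,,,5,,gemcitabine,38,64.2,,13.4,true,
Gurka 2013,2013,xray,5,5,25,,,5,,gemcitabine,10,50,,12.2,true,
Herman 2014,2014,xray,6.6,5,33,,,5,,gemcitabine,49,59,18,13.9,true,
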