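# cohort-csv v1
study_label,year,modality,dose_per_fraction,n_fractions,total_dose,dose_low,dose_high,fractions_per_week,overall_time_days,chemo_category,n_total,os1y_percent,os2y_percent,median_os_months,included_in_fit,exclusion_reason
Moertel 1981 (40 Gy arm),1981,xray,2.0,20,40,,,5,,other,83,46,,11.4,true,
Moertel 1981 (60 Gy arm),1981,xray,2.0,30,60,,,5,,other,85,35,,8.4,true,
Wagener 1996,1996,xray,2.0,20,40,,,5,,other,53,49,,10.8,true,
Ishii 1997,1997,xray,1.8,28,50.4,,,5,,other,20,41.8,,10.3,true,
Fisher 1999,1999,xray,1.8,25,45,,,5,,other,25,32,,9,true,
Andre 2000,2000,xray,1.8,25,45,,,5,,other,32,31,12.5,9,true,
Boz 2001,2001,xray,1.8,33,59.4,,,5,,other,42,30,,9.1,true,
Safran 2001,2001,xray,1.8,28,50.4,,,5,,other,44,30,,8,true,
Li 2003,2003,xray,1.8,31,55.8,50.4,61.2,5,,other,16,31,0,6.7,true,
Morganti 2004,2004,xray,1.7679,28,49.5,39.6,59.4,5,,other,50,31.3,,,true,
Cohen 2005,2005,xray,1.8,33,59.4,,,5,,other,55,31,,8.4,true,
Park 2006,2006,xray,2.0,10,20,,,5,,other,56,37,14.6,10.4,true,
Chauffert 2008,2008,xray,2.0,30,60,,,5,,other,59,32,,8.6,true,
Crane 2009,2009,xray,1.8,28,50.4,,,5,,other,82,47,,11.9,true,
Sudo 2011,2011,xray,1.8,28,50.4,,,5,,other,34,70.6,,16.8,true,
Oberic 2011,2011,xray,1.8,30,54,,,5,,other,20,40,,10,true,
Brunner 2011,2011,xray,1.6909,33,55.8,,,5,,other,35,40,,9.7,true,
Huang 2011,2011,xray,1.7719,32,56.7,50.4,63,5,,other,38,24,,10.2,true,
Malik 2012,2012,xray,1.8,28,50.4,,,5,,other,84,52.6,,10.9,true,
Ikeda 2012,2012,xray,1.8,28,50.4,,,5,,other,60,72,,16.2,true,
Schinchi 2012,2012,xray,1.25,40,50,,,5,,other,50,62,27,14.3,true,
Mukherjee 2013,2013,xray,1.8,28,50.4,,,5,,other,36,79.2,,13.4,true,
Herman 2013 (5-FU arm),2013,xray,1.8,28,50.4,,,5,,other,90,36.7,10.3,10,true,
Herman 2013 (5-FU + TNFerade arm),2013,xray,1.8,28,50.4,,,5,,other,187,41,11.3,10,true,
Ducreaux 2014,2014,xray,1.8,30,54,,,5,,other,51,41,31,9.6,true,
Rembielak 2014,2014,xray,1.8,28,50.4,,,5,,other,21,33,11,7.5,true,
Kwak 2014,2014,xray,1.8,28,50.4,,,5,,other,34,40,10,9,true,
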