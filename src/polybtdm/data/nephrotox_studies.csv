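study,year,n_evaluated,daily_dose_mg,dose_central_type,weight_kg,tox_pct_ge25,tox_pct_ge50,tox_pct_ge75,ssauc_p25,ssauc_p50,ssauc_p75
Ouderkirk,2003,50,110,mean,,,,,43.1,57.4,73.9
Holloway,2006,31,130,median,,22.5,,,47.7,67.4,90.6
Teng,2007,27,62.9,mean,,19.0,,,28.5,42.4,58.9
Pastewski,2008,11,84,mean,,18.0,,,48.1,48.1,60.1
Ramasubban,2008,45,120,mean,,9.0,,,46.6,59.7,81.0
Mendes,2009,114,96.7,mean,,22.0,,,37.5,50.8,70.2
Oliveira,2009,30,100,median,,,,,35.8,51.0,69.2
Elias,2010,235,150,median,,50.6,,,49.4,77.1,117
Kvitko,2011,45,141,mean,,35.0,,,51.1,75.7,108
Esaian,2012,115,100,median,69,48.0,47.8,16.5,46.8,54.2,67.6
Kubin,2012,73,180,median,76.4,60.0,32.9,,45.3,62.2,88.0
Tuon,2013,96,200,median,,20.8,,,52.5,76.8,105
Nandha,2013,32,111,mean,,19.0,18.8,3.13,39.3,57.0,79.8
Akajagbor,2013,67,123,median,74,41.8,28.4,8.96,47.6,62.3,76.4
Phe,2014,104,104,mean,72,23.1,18.3,11.5,39.2,52.8,69.8
Rigatto,2016,410,150,median,66,46.1,23.7,12.7,64.0,83.4,111
Crass (non-CF),2017,49,200.9,mean,83,42.9,14.3,2.0,60.6,81.0,110
Crass (CF),2017,29,124.4,mean,55,34.5,10.3,0,61.4,79.8,101
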