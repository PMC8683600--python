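country,method,mass_kg,n_incidents
KEN,sniffer_dogs,0.5,1
CMR,intelligence,2500,1
HKG,intelligence,8268,1
CHN,intelligence,10560,1
NGA,intelligence,45056,11
CMR,routine_inspection,5050,2
CHN,routine_inspection,62,2
FRA,routine_inspection,250,1
HKG,routine_inspection,28200,7
SGP,routine_inspection,13024,2
VNM,routine_inspection,10624,3
NGA,routine_inspection,1503,4
VNM,scanner,42,1
CHN,scanner,274,2
THA,scanner,587,2
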