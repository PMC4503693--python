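section,area_km2,n_residential,n_structures_total,n_households,n_persons,mean_occupancy
Roma,0.04,4,52,22,139,34.75
Moibawo Farm,0.50,17,43,22,135,7.94
Dodo,0.05,26,88,85,597,22.96
Bo Central,0.07,33,103,51,273,8.27
Toubu,0.02,34,46,88,454,13.35
Kpetewoma,0.20,46,105,94,640,13.91
Komende,0.20,56,258,175,1103,19.70
Salina,0.47,59,231,110,580,9.83
Reservation,2.33,66,252,86,637,9.65
Kindia Town,0.15,102,278,206,1160,11.37
Lewabu,0.48,105,117,170,879,8.37
New York,1.51,116,605,176,1088,9.38
Njai Town,0.22,127,269,388,2298,18.09
New Site south,0.69,136,194,190,1248,9.18
Tengbewabu,0.68,136,233,185,1068,7.85
Yemoh Town,0.40,152,284,289,1858,12.22
Kissi Town,0.20,154,287,400,2490,16.17
Kulanda Town,0.29,197,314,637,3882,19.71
Nduvuibu,0.49,205,343,439,2552,12.45
New London,0.60,208,495,498,2873,13.81
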