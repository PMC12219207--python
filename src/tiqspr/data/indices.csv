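drug,M1,M2,H,HM,F,ABC,R,SC,GA,SO,N
Bromfenac,100,115,9.033,488,258,15.234,9.486,9.71,20.168,72.94,45.686
CIS-UCA,44,46,4.619,196,104,7.289,4.787,4.789,9.651,32.06,20.944
Dexamethasone,168,221,12.747,960,518,22.393,12.963,13.59,29.249,123.985,71.68
Diclofenac,94,107,8.7,452,238,14.458,9.075,9.302,19.302,68.363,43.237
Cyclosporine,32,35,3.133,150,80,5.128,3.304,3.302,6.691,23.435,14.921
Doxycycline,184,237,13.89,1006,532,25.279,14.866,15.507,33.255,134.658,79.837
Estradiol,118,148,9.238,624,328,16.356,9.593,10.269,22.272,85.654,51.899
Fluorometholone,156,201,11.226,874,472,21.428,11.543,12.695,27.376,115.12,66.918
Flurbiprofen,90,104,8.233,438,230,13.71,8.592,8.816,18.342,65.395,41.214
Hydroxychloroquine,110,124,10.8,518,270,17.108,11.134,11.337,23.375,79.519,51.195
Ketorolac,102,123,8.9,402,264,14.934,9.181,9.632,20.476,73.546,46.113
Lifitegrast,226,273,18,1109,587,31.663,18.79,19.854,42.419,159.494,97.947
Methylprednisolone,160,204,11.792,892,480,21.624,12.58,18.85,28.432,117.799,68.886
Minocycline,188,239,14.323,1018,540,26.067,15.333,15.979,34.174,137.766,81.882
Nepafenac,94,108,8.733,454,238,14.417,9.092,8.782,19.342,68.223,43.214
Pranoprofen,102,121,8.833,506,264,15.015,9.147,9.605,20.396,73.826,46.158
Rebamipide,134,155,11.933,654,344,20.184,12.435,12.893,27.047,97.401,61.102
Rimexolone,160,207,11.811,846,480,21.603,12.591,13.228,28.93,117.69,68.869
Rivoglitazone,150,177,13.1,740,386,22.086,13.529,14.207,30.157,108.512,68.015
Tacrolimus,282,325,24.838,1427,750,41.647,26.074,26.697,45.219,205.545,127.279
Tetracycline,178,226,13.471,964,512,24.614,14.406,15.062,32.292,130.425,77.45
Piperidine,106,121,10.166,498,256,16.291,10.326,10.788,22.663,75.987,49.259
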