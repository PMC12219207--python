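drug,BP,MR,P,MV,E,C,MW
Bromfenac,472.23,79.1,31.4,213.5,88.9,366,334.16
CIS-UCA,371.97,36.2,14.4,96.6,75.5,156,138.12
Dexamethasone,508.92,100.2,39.7,296,98,805,392.5
Diclofenac,423.77,76.5,30.3,206.8,70.1,304,296.1
Cyclosporine,281.12,22.5,8.9,79.9,NA,92.9,102.09
Doxycycline,753.5,109,43.2,271.1,116.5,956,444.4
Estradiol,395.47,79.5,31.5,232.6,74.2,382,272.4
Fluorometholone,465.47,98.7,39.1,298.9,92.2,787,376.5
Flurbiprofen,380.71,66.6,26.4,203.6,65.8,286,244.26
Hydroxychloroquine,455.39,99,39.2,285.4,83,331,335.9
Ketorolac,414.83,70.5,28,191.2,80.1,376,255.27
Lifitegrast,NA,153.7,60.94,416,123.7,1100,615.5
Methylprednisolone,513.91,100.1,39.7,291.5,98.5,754,374.5
Minocycline,743.4,116,46,294.6,122.5,NA,NA
Nepafenac,470.54,86,29.1,203.4,84.6,337,254.28
Pranoprofen,405.34,69.2,NA,195,76.6,346,255.27
Rebamipide,641.76,95.1,37.7,265.8,106.9,598,370.8
Rimexolone,459.38,106.3,42.1,329.2,89.5,749,370.5
Rivoglitazone,729.27,106.5,42.2,280.9,98.4,584,397.4
Tacrolimus,871.7,214.1,84.9,673.1,143.9,1480,804
Tetracycline,745.32,106.9,42.4,266.3,113,971,444.4
Piperidine,400.8,85.4,33.9,252.7,69.1,300,285.4
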