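activity,Bed-to-Toilet,Chores,Desk_Activity,Dining_Rm_Activity,Eve_Meds,Guest_Bathroom,Kitchen_Activity,Leave_Home,Master_Bathroom,Meditate,Watch_TV,Sleep,Read,Morning_Meds,Master_Bedroom_Activity,printed_recall
Bed-to-Toilet,95,0,0,0,0,0.3,0,0,0,0,0,0,0,1,0.3,98.344
Chores,0,98,0,0,0,0,1,0.2,0.05,0,0,0,0,0,0,98.741
Desk_Activity,0,0,98,0,0,0,0,0,0,0,2,0.3,0,0,0,97.707
Dining_Rm_Activity,0,0.8,0,99,0,2,0,0.1,0,0,0,0,0,0,0,97.154
Eve_Meds,0,0,0,0,100,0,0,0,0,0,0,0,0,0,0,100.000
Guest_Bathroom,0,0,0,0.3,0.2,97,0,1.2,1,0,0,0,0,0,0,97.292
Kitchen_Activity,0,1.2,0,1.2,0,0,97,0,0.3,0,0,0,0.6,0,0,96.710
Leave_Home,0,0,0,2,0,0,1.2,96,0.9,0,0,0,1,0,0,94.955
Master_Bathroom,0,1.1,0,0,0,0,1,0.4,99,0,0,0,0.2,0,0,97.345
Meditate,0,0,0,0,0.3,0,0,0,0,98,0.6,0,0,0,0,99.090
Watch_TV,0,0,0,0,0,0,0,0,0,0,99,0,0,0,0,100.000
Sleep,2,0,0,0,0,0,0,0,0,0,0,97,0,1,0.5,96.517
Read,0,0,0,1,0,1,0,0,0,0,0,0,96,0,0.9,97.068
Morning_Meds,1,0,0.5,0,0,0,0.8,0,0,0,0,0,0,95,0.033,97.603
Master_Bedroom_Activity,0,0,0,0,0,0,0,0,0,0,0,0,0,0.2,95,99.790
printed_precision,96.939,96.934,99.492,95.652,99.502,96.710,96.040,98.059,97.778,100.000,97.441,99.692,98.160,97.737,98.208,
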