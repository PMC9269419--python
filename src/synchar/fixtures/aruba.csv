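activity,Meal_Preparation,Relax,Eating,Work,Sleeping,Wash_Dishes,Bed_to_Toilet,Enter_Home,Leave_Home,Housekeeping,Resperate,printed_recall
Meal_Preparation,98,1.3,0.7,0,0,1.1,0,0,0,0,0,96.934
Relax,0,98,0,1,1,0,0.3,0,0,0,0.1,97.610
Eating,0,0,97,0,0,1,0,0,0.5,0.1,0,98.377
Work,0.6,1.2,0.2,95,0.1,0.6,0.4,1,0.3,0,0,95.573
Sleeping,0,0,0,0,97,0,0,1,0,0,0,98.980
Wash_Dishes,0,0,0,0.3,0.2,99,0,0,0,0,0,99.497
Bed_to_Toilet,0,0,0,0,0,0,98,1,0,0,0,98.990
Enter_Home,0,0.4,0,0,2,0,1.54,98,0,0,0,96.135
Leave_Home,0,0,0,0,0,0,0,0,100,0,0,100.000
Housekeeping,0.2,0,0,0,0,0,0,0,0,98,0,99.796
Resperate,0,0,0,0,0,0,0,0,0,0,97,100.000
printed_precision,99.190,97.126,99.081,98.650,96.710,97.345,97.765,97.030,99.206,99.898,99.897,
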