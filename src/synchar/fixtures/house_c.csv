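activity,Brushing Teeth,Drinking,Dressing,Eating,Leaving House,Medication,Preparing Breakfast,Preparing Lunch,Preparing Dinner,Relax,Sleeping,Showering,Snacks,Shaving,Toileting,Others,printed_recall
Brushing Teeth,95,0,0,0,0,0.3,0,0,0,0,0,0,0,0.3,0.3,0.5,98.548
Drinking,0,98,0,0,0,0,1,0.2,0.05,0,0,0,0,0,0,0.2,98.542
Dressing,0,0,98,0,0,0,0,0,0,0,0.5,0.3,0,0,0,0.1,99.090
Eating,0,0.3,0,99,0,2,0,0.1,0,0,0,0,0,0,0,0.05,97.585
Leaving House,0,0,0,0,100,0,0,0,0,0,0,0,0,0,0,0.1,99.900
Medication,0,0,0,0.3,0.2,97,0,0.2,1,0,0,0,0,0,0,0.4,97.881
Preparing Breakfast,0,0.2,0,0.2,0,0,97,0,0.3,0,0,0,0.3,0,0,0.5,98.477
Preparing Lunch,0,0,0,2,0,0,1.2,96,0.9,0,0,0,0.5,0,0,0.1,95.333
Preparing Dinner,0,0.1,0,0,0,0,1,0.4,99,0,0,0,0.2,0,0,0.3,98.020
Relax,0,0,0,0,0.3,0,0,0,0,98,0.6,0,0,0,0,0.5,98.592
Sleeping,0,0,0,0,0,0,0,0,0,0,99,0,0,0,0,0.43,99.568
Showering,1,0,0,0,0,0,0,0,0,0,0,97,0,1,0.5,0.2,97.292
Snacks,0,0,0,1,0,1,0,0,0,0,0,0,96,0,0.4,0.1,97.462
Shaving,1,0,0.5,0,0,0,0.8,0,0,0,0,0,0,95,0.033,0.4,97.204
Toileting,0,0,0,0,0,0,0,0,0,0,0,0,0,0.2,93,0.11,99.668
Others,0.2,0,0.1,0.2,0.3,0.2,0.3,0.11,0.2,0.1,0,0.58,0.3,0.5,0.2,93,96.583
printed_precision,97.737,99.391,99.391,96.397,99.206,96.517,95.755,98.959,97.585,99.898,98.901,99.101,98.664,97.938,98.483,95.886,
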