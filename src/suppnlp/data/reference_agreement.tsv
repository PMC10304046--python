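category	precision	recall	f1
calcium	0.81	0.84	0.83
chondroitin	0.78	0.64	0.70
creatine	0.77	0.76	0.77
fiber	0.80	0.67	0.73
fish oil	0.79	0.50	0.61
folic acid	0.70	0.27	0.39
iron	0.81	0.68	0.74
magnesium	0.81	0.67	0.73
melatonin	0.68	0.50	0.58
multivitamin	0.91	0.26	0.40
potassium	0.76	0.67	0.71
tea	0.72	0.66	0.69
thiamine	0.78	0.33	0.47
vitamin a	0.77	0.65	0.71
vitamin b12	0.94	0.28	0.43
vitamin d2	0.88	0.47	0.61
vitamin d3	0.94	0.28	0.43
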