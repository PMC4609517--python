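outcome,sex,category,central,lower,upper
mortality,combined,low,0.95,0.92,0.98
mortality,combined,high,0.90,0.85,0.96
CHD,male,low,0.99,0.91,1.08
CHD,male,high,0.99,0.90,1.10
CHD,female,low,0.95,0.83,1.08
CHD,female,high,0.80,0.69,0.92
type2_diabetes,combined,low,0.77,0.58,1.02
type2_diabetes,combined,high,0.69,0.54,0.88
hypertension,combined,low,0.76,0.61,0.94
hypertension,combined,high,0.69,0.58,0.83
stroke,male,low,0.94,0.83,1.06
stroke,male,high,0.88,0.77,1.02
stroke,female,low,0.88,0.77,1.01
stroke,female,high,0.87,0.75,1.01
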