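factor_id,label,level,pooled_or,ci_low,ci_high
male,Male sex,present,1.73,1.24,2.41
bariatric_surgery,Bariatric surgery,present,0.39,0.21,0.71
myopia,Myopia,present,0.70,0.58,0.85
lipid_lowering,Lipid-lowering drug use,lt3y,0.37,0.13,1.02
lipid_lowering,Lipid-lowering drug use,gt3y,0.80,0.64,1.01
fpg,Elevated fasting plasma glucose,present,1.25,1.00,1.55
duration,Long diabetes duration,present,1.19,1.11,1.27
hba1c,Elevated HbA1c,present,1.45,1.20,1.75
intensive_control,Intensive glycemic control,present,0.67,0.26,1.73
hypertension,Hypertension,present,1.50,1.20,1.87
insulin,Insulin therapy,present,1.99,1.34,2.95
rural,Rural residence,present,1.22,1.10,1.35
smoking,Smoking,present,0.68,0.86,0.98
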