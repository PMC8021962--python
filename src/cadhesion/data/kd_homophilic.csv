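cadherin,kd_molar,cadherin_type,specificity_group,source
Cdh1,96.5e-6,type I,none,analytical ultracentrifugation (E-cadherin EC1-2)
Cdh2,25.8e-6,type I,none,analytical ultracentrifugation (N-cadherin EC1-2)
Cdh3,80.0e-6,type I,none,synthetic-placeholder
Cdh4,60.0e-6,type I,none,synthetic-placeholder
Cdh6,5.2e-6,type II,A,synthetic-placeholder
Cdh9,9.8e-6,type II,A,synthetic-placeholder
Cdh10,4.3e-6,type II,A,synthetic-placeholder
Cdh7,11.0e-6,type II,B,synthetic-placeholder
Cdh12,14.0e-6,type II,B,synthetic-placeholder
Cdh18,13.0e-6,type II,B,synthetic-placeholder
Cdh20,7.7e-6,type II,B,synthetic-placeholder
Cdh22,9.0e-6,type II,B,synthetic-placeholder
Cdh8,6.0e-6,type II,C,synthetic-placeholder
Cdh11,2.9e-6,type II,C,synthetic-placeholder
Cdh24,8.1e-6,type II,C,synthetic-placeholder
Cdh13,50.0e-6,atypical,none,synthetic-placeholder
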