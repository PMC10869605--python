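compound_id,predicted_ic50,docking_total_score
44,0.7052,6.3154
44a,0.5546,7.7065
44b,0.5516,6.7748
44c,0.5036,6.8673
44d,0.4402,6.4417
44e,0.3561,6.3002
44f,0.3951,6.8984
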