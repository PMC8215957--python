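model_version,metric,value,grade
initial_no_boot,magnitude,0.474,Poor
initial_no_boot,phase,0.608,Fair
initial_no_boot,slope,0.757,Fair
calibrated_no_boot,magnitude,0.886,Good
calibrated_no_boot,phase,0.854,Good
calibrated_no_boot,slope,0.786,Fair
calibrated_boot,magnitude,0.958,Excellent
calibrated_boot,phase,0.786,Fair
calibrated_boot,slope,0.970,Excellent
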