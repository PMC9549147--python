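strategy,cost_thb,qaly
standard,161282,2.39
standard_plus_glucosamine_before_diclofenac_ppi,150878,3.26
standard_plus_glucosamine_after_diclofenac_ppi,192561,3.26
standard_plus_etoricoxib,418268,4.44
standard_plus_etoricoxib_plus_glucosamine_before_diclofenac_ppi,366819,4.98
standard_plus_etoricoxib_plus_glucosamine_after_diclofenac_ppi,431478,4.98
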