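name,template,base_value
benzene,c1cc({a})cc({b})c1,5.0
pyridine,c1cc({a})cc({b})n1,4.6
cyclohexane,C1CC({a})CC({b})C1,4.2
furan,c1c({a})cc({b})o1,4.8
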