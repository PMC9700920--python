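component,min,max,points
los,0,0,0
los,1,1,1
los,2,2,2
los,3,3,3
los,4,6,4
los,7,13,5
los,14,,7
acuity,0,0,0
acuity,1,,3
charlson,0,0,0
charlson,1,1,1
charlson,2,2,2
charlson,3,3,3
charlson,4,,5
ed_visits,0,0,0
ed_visits,1,1,1
ed_visits,2,2,2
ed_visits,3,3,3
ed_visits,4,,4
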