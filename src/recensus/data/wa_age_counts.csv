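source,age_group,count
census,0-9,302
census,10-14,498
census,15-19,712
wacdd,0-9,285
wacdd,10-14,384
ndss,0-9,310
ndss,10-19,1410
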