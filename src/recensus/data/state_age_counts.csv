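state,age_group,census,register
NSW,0-9,766,830
VIC,0-9,689,750
QLD,0-9,560,570
WA,0-9,302,310
SA,0-9,193,190
TAS,0-9,71,80
ACT,0-9,44,50
NT,0-9,20,
NSW,10-19,3494,3770
VIC,10-19,2746,3080
QLD,10-19,2505,2970
WA,10-19,1210,1410
SA,10-19,887,980
TAS,10-19,272,310
ACT,10-19,211,220
NT,10-19,144,160
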