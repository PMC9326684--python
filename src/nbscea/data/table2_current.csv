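component,n_persons,year1,year2,year3,year4,year5,total
No Screening,99989,0,0,0,0,0,0
Clinical SMA,9.1,4824852,2124069,1908986,1674157,1485020,12017084
Clinical SCID,1.6,382024,9264,8167,7203,6357,413014
Early SCID by family history,0.4,49024,1550,1374,1219,1083,54250
Total budget,100000,5255900,2134883,1918527,1682579,1492460,12484349
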