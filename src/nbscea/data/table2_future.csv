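component,n_persons,year1,year2,year3,year4,year5,total
Screening,99989,558371,0,0,0,0,558371
Screened SMA,8.5,13759906,518371,390943,357220,341565,15368005
Clinical SMA,0.6,318122,140049,125867,110384,97913,792335
Screened SCID,2,245120,7750,6870,6097,5413,271250
Late SCID,0.01,2388,58,51,45,40,2581
Total budget,100000,,666227,523731,473746,444931,16992542
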