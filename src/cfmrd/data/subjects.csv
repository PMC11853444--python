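subject_id,diagnosis,relapse_day,death_day,last_followup_day,consolidation_start_day,adverse_at_diagnosis,status_note
001,AML,,59,59,,true,"Expired, regimen-related toxicity, day 59"
002,t-MDS,170,,365,,true,"Alive, >day 365"
003,MDS,,,365,,true,"Alive, >day 365"
004,AML,,357,357,51,false,"Expired, infection, day 357"
005,t-MDS,,,365,121,true,"Alive, >day 365"
006,2nd-AML (CMML),,,365,,true,"Alive, >day 365"
007,2nd-AML (MDS),62,250,250,,true,"Expired, relapse, day 250"
008,AML,,,365,91,true,"Alive, >day 365"
009,AML,168,285,285,76,true,"Expired, relapse, day 285"
010,2nd-AML,52,125,125,,true,"Expired, relapse, day 125"
011,2nd-AML (MDS),,,365,88,true,"Alive, >day 365"
012,MDS,167,,365,,true,"Alive, relapse, day 347"
013,MDS,139,,365,,true,"Alive, >day 365"
015,AML,,,365,35,true,"Alive, >day 365"
016,MDS,,268,268,89,true,"Expired, sepsis, day 268"
017,CML,,,365,52,true,"Alive, >day 365"
018,2nd-AML (BrCa),,,365,,true,"Alive, >day 365"
019,2nd-AML (MF),,,365,,true,"Alive, >day 365"
020,AML,,,365,,true,"Alive, >day 365"
021,MDS,,,365,77,true,"Alive, >day 365"
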