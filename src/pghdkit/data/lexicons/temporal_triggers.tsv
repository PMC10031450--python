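# Relative-date trigger phrases. The canonical column is a semantic code:
# D<offset> = reference date + offset days; PHRASAL = unresolvable phrasal
# referent (kept as raw text, never guessed).
# term	canonical	concept_id
yesterday	D-1	TT:yesterday
today	D0	TT:today
tonight	D0	TT:tonight
this morning	D0	TT:this_morning
this afternoon	D0	TT:this_afternoon
this evening	D0	TT:this_evening
last night	D-1	TT:last_night
last week	D-7	TT:last_week
a week ago	D-7	TT:week_ago
a few days ago	PHRASAL	TT:few_days_ago
few days ago	PHRASAL	TT:few_days_ago
a couple of days ago	PHRASAL	TT:couple_days_ago
a couple days ago	PHRASAL	TT:couple_days_ago
the other day	PHRASAL	TT:other_day
a while ago	PHRASAL	TT:while_ago
recently	PHRASAL	TT:recently
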