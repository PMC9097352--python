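#mciscreen-dictionary
#version: toy-1.0
#fields: cui	role	max_gap	description	patterns
WANDER	feature	2	Wandering or getting lost	wander
DECLINE	feature	2	Declining memory or cognitive ability	loss cognitive ability|memory decline
FORGET	feature	2	Forget / can't remember	forget
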