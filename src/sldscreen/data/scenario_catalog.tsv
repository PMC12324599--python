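id	name	dialogic	included
S1	Construction Task	0	0
S2	Telling a Story from a Book	0	0
S3	Description of a Picture	1	1
S4	Conversation and Reporting	1	1
S5	Current Work and School	1	1
S6	Social Difficulties and Annoyance	1	1
S7	Emotions	1	1
S8	Demonstration Task	0	0
S9	Cartoons	1	1
S10	Break	0	0
S11	Daily Living	1	1
S12	Friends, Relationships, and Marriage	1	1
S13	Loneliness	1	1
S14	Plans and Hopes	1	1
S15	Creating a Story	1	1
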