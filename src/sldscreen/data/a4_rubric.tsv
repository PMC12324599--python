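score	description
0	Rarely or never uses stereotyped or idiosyncratic words or phrases. The subject demonstrates typical language use without noticeable patterns of repetition or unusual phrasing.
1	Uses words or phrases that are more repetitive or formal compared to most individuals at a similar level of expressive language, though not obviously odd. This category also includes occasional stereotyped utterances or odd use of words or phrases, while still showing substantial spontaneous and flexible language use.
2	Often uses stereotyped utterances or odd words or phrases, with some other spontaneous language. The subject displays a noticeable pattern of repetitive or unusual phrasing that stands out in conversation.
3	Frequently uses odd or stereotyped speech and rarely exhibits non-stereotyped spontaneous speech. The language is predominantly characterized by repetitive, formal, or idiosyncratic expressions, with very little flexibility or spontaneity.
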