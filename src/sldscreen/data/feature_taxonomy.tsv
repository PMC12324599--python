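id	name	explanation	critical
F1	Echoic Repetition	The individual mimics verbatim what has been said by others, including the examiner, or recites phrases from external sources like advertisements or movie scripts, showing a delayed echo response.	1
F2	Unconventional Content	The speech contains peculiarly chosen content or contextually odd phrasing, such as using ‘unfreshness through household’ for lack of novelty, ‘mideast’ instead of ‘midwest’ for U.S. states, or describing entry into a building as ‘through various apertures’.	0
F3	Pronoun Displacement	Incorrectly substitutes personal pronouns, using ‘you’ in place of ‘I’, or refers to themselves in the third person, either by pronouns like ‘he/she’ or by their own name.	0
F4	Incongruous Humor Timing	Incorporates humorous or comedic expressions inappropriately during discussions meant to be serious, showing a misalignment between the content’s emotional tone and the context.	0
F5	Formalistic Language Use	Employs an overly formal or archaic language style that seems lifted from written texts, legal documents, or old literature, rather than engaging in conversational speech. Examples include elaborate ways of expressing simple ideas or feelings.	0
F6	Superfluous Phrase Attachment	Attaches redundant phrases or filler expressions to their speech without contributing any substantive meaning or context, such as ‘you know what I mean’ or ‘as they say,’ indicating a habit rather than intentional emphasis.	0
F7	Excessive Social Phrasing	Utilizes conventional social expressions excessively or inappropriately, responding with phrases like ‘oh, thank you’ in contexts where it does not fit or preempting social gestures not yet performed by the interlocutor.	0
F8	Monotone Social Expression	Reiterates social phrases with an unchanged, monotonous intonation, indicating a lack of genuine emotional engagement or variability in social interactions.	0
F9	Stereotyped Media Quoting	Quotes lines from commercials, movies, or TV shows in a highly stereotypical manner, employing a canned intonation that mimics the original source closely, suggesting a reliance on external media for verbal expressions.	1
F10	Clichéd Verbal Substitutions	Resorts to well-known sayings or clichés in lieu of engaging in direct conversational responses, using phrases like ‘circle of life’ or ‘ready to roll’ as stand-ins for more personalized communication.	0
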