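# social phrases whose verbatim repetition signals F8
nice to talk with you
nice to meet you
how are you today
have a nice day
good to see you
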