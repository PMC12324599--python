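# redundant filler tags (F6)
you know what i mean
as they say
or whatever
whatever
like, like
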