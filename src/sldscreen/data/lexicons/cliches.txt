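# cliche substitutions for direct answers (F10)
pretty much
circle of life
ready to roll
it is what it is
at the end of the day
when life gives you lemons
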