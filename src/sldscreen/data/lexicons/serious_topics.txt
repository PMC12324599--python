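# serious-topic keywords (context for F4)
sick
hospital
funeral
died
passed away
sad
lonely
angry
hurt
worried
problem
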