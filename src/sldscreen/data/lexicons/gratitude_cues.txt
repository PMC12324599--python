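# examiner cues that make a courtesy phrase fitting (context for F7)
thank
thanks
gift
here you go
congratulations
well done
very kind
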