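# markers of joking delivery (F4, must co-occur with a serious topic)
just kidding
just joking
ha ha
haha
knock knock
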