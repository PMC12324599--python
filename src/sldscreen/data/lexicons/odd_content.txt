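# anomalous noun phrases / contextually odd content (F2)
unfreshness through household
through various apertures
mideast states
zillion blocks matching
a lounge and dirty matching
stupid schools for the developing angry
crooked crowded year people
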