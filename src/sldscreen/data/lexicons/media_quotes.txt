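# stereotyped media lines (F9)
to infinity and beyond
may the force be with you
just keep swimming
i'll be back
gas movies
triggered the trip, pregnant sound effects
why so serious
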