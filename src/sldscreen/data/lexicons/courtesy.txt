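# stock courtesy phrases (F7)
thank you
thanks a lot
much obliged
you're welcome
so kind of you
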