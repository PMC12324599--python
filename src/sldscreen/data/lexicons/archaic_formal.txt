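# overly formal or archaic register (F5)
henceforth
thusly
forthwith
hitherto
heretofore
shall endeavor
comport myself
whomsoever
most esteemed
i do declare
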