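species,paralog,lambda_max_nm
spotted flounder,Sws2a,485.4
spotted flounder,Sws2b,415.8
slime flounder,Sws2a,451.9
olive flounder,Sws2a,465.6
guppy,Sws2a,438
guppy,Sws2b,408
medaka,Sws2a,439
medaka,Sws2b,405
bluefin killifish,Sws2a,448
bluefin killifish,Sws2b,397
zebrafish,Sws2,416
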