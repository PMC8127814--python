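(Zv9:0.35,(hipCom0:0.22,((fr3:0.09,gasAcu1:0.08):0.05,(oryLat2:0.1,oreNil2:0.09):0.04):0.06):0.12);
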