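(((TCF7,LEF1)tcf7_lef1,(TCF7L1,TCF7L2)tcf7l1_l2)preWGD,UrochordateTCF,CephalochordateTCF,AmbulacrariaTCF)root;
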