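2,3,2,2,1
mini panel,,P1,P2
Sample,Pop,LocA,,,,LocB,,,
S1,P1,173,175,175,180,200,202,0,0
S2,P1,173,173,173,173,0,0,0,0
S3,P2,175,180,0,0,202,204,206,0
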