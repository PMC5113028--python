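glove,label,mechanism,av_certification,grip_strength_reduction_pct
gel,A,Viscoelastic Gel,Not classified as AV glove,40
bladder,B,Air Bladder,Classified as AV glove,30
bubble,C,Air Bubble,Marginally classified as AV glove,34
neoprene,D,Neoprene-dipped,Not classified as AV glove,26
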