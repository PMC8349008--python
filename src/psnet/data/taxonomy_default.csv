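code,group
207Q00000X,pcp
207R00000X,pcp
208D00000X,pcp
363L00000X,pcp
363LF0000X,pcp
363LA2200X,pcp
364S00000X,pcp
2084P0800X,psychiatrist
2084P0804X,psychiatrist
2084P0805X,psychiatrist
2084A0401X,psychiatrist
103T00000X,psychologist
103TC0700X,psychologist
103TC2200X,psychologist
103TB0200X,psychologist
1041C0700X,bh_specialist
101YM0800X,bh_specialist
101YP2500X,bh_specialist
106H00000X,bh_specialist
101Y00000X,bh_specialist
104100000X,bh_specialist
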