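acid,group,mean,sd,letters
C10:0,NX,0.004,0.001,b
C10:0,GS,0.008,0.002,a
C10:0,IM,0.004,0.001,b
C12:0,NX,0.008,0.003,b
C12:0,GS,0.030,0.002,a
C12:0,IM,0.008,0.003,b
C14:0,NX,0.081,0.005,c
C14:0,GS,0.251,0.007,a
C14:0,IM,0.089,0.005,b
C15:0,NX,0.020,0.004,b
C15:0,GS,0.025,0.004,a
C15:0,IM,0.023,0.003,ab
C16:0,NX,0.711,0.009,c
C16:0,GS,0.959,0.010,a
C16:0,IM,0.912,0.009,b
C17:0,NX,0.085,0.008,b
C17:0,GS,0.053,0.008,c
C17:0,IM,0.101,0.008,a
C18:0,NX,0.609,0.011,b
C18:0,GS,0.533,0.010,c
C18:0,IM,0.727,0.010,a
C24:0,NX,0.005,0.002,
C24:0,GS,0.006,0.002,
C24:0,IM,0.005,0.002,
C14:1,NX,0.003,0.001,b
C14:1,GS,0.009,0.001,a
C14:1,IM,0.003,0.001,b
C16:1,NX,0.078,0.004,c
C16:1,GS,0.115,0.002,a
C16:1,IM,0.085,0.006,b
C18:1n9c,NX,1.181,0.011,c
C18:1n9c,GS,1.279,0.003,b
C18:1n9c,IM,1.429,0.013,a
C20:1n9,NX,0.003,0.001,
C20:1n9,GS,0.004,0.002,
C20:1n9,IM,0.004,0.001,
C18:2n6c,NX,0.313,0.002,a
C18:2n6c,GS,0.247,0.002,c
C18:2n6c,IM,0.308,0.002,b
C18:3n3,NX,0.004,0.002,b
C18:3n3,GS,0.015,0.002,a
C18:3n3,IM,0.006,0.002,b
C20:2,NX,0.002,0.001,
C20:2,GS,0.002,0.001,
C20:2,IM,0.002,0.001,
C20:3n6,NX,0.010,0.001,a
C20:3n6,GS,0.005,0.001,b
C20:3n6,IM,0.011,0.001,a
C20:4n6,NX,0.132,0.003,a
C20:4n6,GS,0.089,0.004,b
C20:4n6,IM,0.135,0.003,a
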