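[&R] (BC,(PIND,(MpPIN_WXY,((Lyco1,Lyco2),(((PIN5,(PINI,PIN12)),((((PINK,PINL),PINM),PINN),PIN6)),(PINJ,(PINE,(PINF,(PING,(PINH,((PIN1,PIN9),(PIN11,(PIN2,(PIN3,PIN8))))))))))))));
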