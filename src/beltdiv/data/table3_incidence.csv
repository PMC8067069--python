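unit,Macrotermes gilvus,Microtermes insperatus,Odontotermes grandiceps,Odontotermes javanicus,Odontotermes karnyi,Odontotermes bilitoni,Odontotermes longignathus,Odontotermes sp1,Pericapritermes semarangi,Pericapritermes mohri,Pericapritermes latignathus,Pericapritermes A,Pericapritermes B
A,1,1,1,0,0,0,0,0,1,0,0,1,1
B,1,1,1,1,0,0,0,1,0,1,0,0,0
C,1,1,1,1,1,1,1,0,0,1,1,0,0
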