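species,genus,functional_group
Macrotermes gilvus,Macrotermes,IIf
Microtermes insperatus,Microtermes,IIf
Odontotermes grandiceps,Odontotermes,IIf
Odontotermes javanicus,Odontotermes,IIf
Odontotermes karnyi,Odontotermes,IIf
Odontotermes bilitoni,Odontotermes,IIf
Odontotermes longignathus,Odontotermes,IIf
Odontotermes sp1,Odontotermes,IIf
Pericapritermes semarangi,Pericapritermes,III
Pericapritermes mohri,Pericapritermes,III
Pericapritermes latignathus,Pericapritermes,III
Pericapritermes A,Pericapritermes,III
Pericapritermes B,Pericapritermes,III
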