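row_label,col_label,r,sig_code
VM,DS,0.54,.001
VM,TMT,0.29,.01
VM,VF,0.42,.001
VM,SC,0.49,.001
VM,TL,0.27,.05
DS,TMT,0.39,.001
DS,VF,0.53,.001
DS,SC,0.63,.001
DS,TL,0.41,.001
TMT,VF,0.43,.001
TMT,SC,0.53,.001
TMT,TL,0.25,.05
VF,SC,0.56,.001
VF,TL,0.50,.001
SC,TL,0.43,.001
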