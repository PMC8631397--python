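row_label,col_label,r,sig_code
ASLs,VM,-0.17,ns
ASLs,DS,-0.27,.01
ASLs,TMT,-0.03,ns
ASLs,VF,-0.21,.05
ASLs,SC,-0.46,.001
ASLs,TL,-0.21,.05
ASELs,VM,-0.14,ns
ASELs,DS,-0.07,ns
ASELs,TMT,0.08,ns
ASELs,VF,-0.02,ns
ASELs,SC,-0.08,ns
ASELs,TL,0.01,ns
ASEs,VM,-0.09,ns
ASEs,DS,-0.41,.001
ASEs,TMT,-0.04,ns
ASEs,VF,-0.20,.1
ASEs,SC,-0.35,.001
ASEs,TL,-0.06,ns
GnGLs,VM,-0.09,ns
GnGLs,DS,-0.24,.05
GnGLs,TMT,-0.14,ns
GnGLs,VF,-0.23,.05
GnGLs,SC,-0.44,.001
GnGLs,TL,-0.07,ns
GnGELs,VM,-0.06,ns
GnGELs,DS,-0.16,ns
GnGELs,TMT,-0.05,ns
GnGELs,VF,-0.24,.05
GnGELs,SC,-0.38,.001
GnGELs,TL,-0.08,ns
GnGEs,VM,-0.24,.05
GnGEs,DS,-0.24,.05
GnGEs,TMT,-0.03,ns
GnGEs,VF,-0.02,ns
GnGEs,SC,-0.24,.05
GnGEs,TL,-0.12,ns
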