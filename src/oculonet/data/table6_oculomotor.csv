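row_label,col_label,r,sig_code
ASLs,ASELs,0.31,.01
ASLs,ASEs,0.53,.001
ASLs,GnGLs,0.63,.001
ASLs,GnGELs,0.51,.001
ASLs,GnGEs,0.29,.01
ASELs,ASEs,0.02,ns
ASELs,GnGLs,0.30,.01
ASELs,GnGELs,0.33,.01
ASELs,GnGEs,-0.05,ns
ASEs,GnGLs,0.44,.001
ASEs,GnGELs,0.33,.01
ASEs,GnGEs,0.41,.001
GnGLs,GnGELs,0.71,.001
GnGLs,GnGEs,0.07,ns
GnGELs,GnGEs,0.08,ns
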