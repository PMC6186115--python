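symbolic_code,kind,role,user_code
INSERT_PORT,proc,insertion,INSERT_PORT
REMOVE_PORT,proc,removal,REMOVE_PORT
REPAIR_PORT,proc,repair,REPAIR_PORT
REPLACE_PART,proc,replace_part,REPLACE_PART
REPLACE_FULL,proc,replace_full,REPLACE_FULL
DX_MECH_COMPL,dx,mechanical,DX_MECH_COMPL
DX_CVC_INFECT_OTHER,dx,infection_other,DX_CVC_INFECT_OTHER
DX_CVC_INFECT_LOCAL,dx,infection_local,DX_CVC_INFECT_LOCAL
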