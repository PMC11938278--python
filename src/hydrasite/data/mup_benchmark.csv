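ligand,pdb_id,WATsiteNN,WATsite,experimental,MM-GB/SA
PE9,1ZND,-24.4,-23.4,-23.1,-33.9
HE2,1ZNE,-27.6,-27.2,-28.3,-39.0
HE4,1ZNG,-33.1,-23.2,-32.5,-27.2
OC9,1ZNH,-36.2,-36.4,-35.6,-23.2
F09,1ZNK,-34.8,-36.4,-38.8,-38.1
IBMP,1QY1,-40.3,-36.8,-38.5,-30.2
IPMP,1QY2,-35.3,-41.1,-33.9,-28.2
SBT,1IO6,-35.3,-35.9,-35.3,-38.4
PT,1IO6,-32.0,-39.4,-34.3,-34.7
IPT,1IO6,-31.0,-35.9,-32.6,-34.2
ET,1IO6,-29.8,-29.5,-29.2,-30.5
MT,1IO6,-26.5,-21.6,-24.2,-28.9
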