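# Synthetic stand-in unfolded-state heat-capacity contributions (J/(K mol) per residue). Values emulate the rise-then-flatten temperature dependence of unfolded polypeptides; they are NOT transcribed from a published table. Supply your own table or the c coefficient directly for real analyses.
residue,cp_5C,cp_25C,cp_50C,cp_75C,cp_100C,cp_125C
A,114.4,130.0,143.0,149.5,152.1,152.8
C,132.0,150.0,165.0,172.5,175.5,176.2
D,114.4,130.0,143.0,149.5,152.1,152.8
E,145.2,165.0,181.5,189.7,193.0,193.9
F,255.2,290.0,319.0,333.5,339.3,340.8
G,74.8,85.0,93.5,97.7,99.4,99.9
H,176.0,200.0,220.0,230.0,234.0,235.0
I,215.6,245.0,269.5,281.8,286.6,287.9
K,220.0,250.0,275.0,287.5,292.5,293.8
L,211.2,240.0,264.0,276.0,280.8,282.0
M,202.4,230.0,253.0,264.5,269.1,270.2
N,127.6,145.0,159.5,166.8,169.6,170.4
P,132.0,150.0,165.0,172.5,175.5,176.2
Q,158.4,180.0,198.0,207.0,210.6,211.5
R,237.6,270.0,297.0,310.5,315.9,317.2
S,105.6,120.0,132.0,138.0,140.4,141.0
T,145.2,165.0,181.5,189.7,193.0,193.9
V,176.0,200.0,220.0,230.0,234.0,235.0
W,290.4,330.0,363.0,379.5,386.1,387.8
Y,246.4,280.0,308.0,322.0,327.6,329.0
TERMINAL,79.2,90.0,99.0,103.5,105.3,105.8
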