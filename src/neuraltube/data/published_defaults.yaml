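# Published default parameter set.
#
# c1..c13, n1..n13, delta1..delta4: the optimised in-vitro network
# (rate constants, Hill coefficients, degradation rates; see
# neuraltube.params.EDGE_PARAM_INDEX for the edge <-> index mapping).
# c14..c16, n14..n16, delta5: the WNT-driven buffer node of the in-vivo
# system.  The dorsoventral block holds the Gli/Pax6/Olig2/Nkx2.2
# constants; the morphogen block the diffusion/decay/source constants.
# Levels are dimensionless; CT is in uM, diffusivities in um^2/s.
#
# This file is the single source of truth for the defaults; see
# docs/methods.md for how the in-vitro values were established and which
# dorsoventral constants are package choices rather than published ones.
c1: 0.01
c2: 58.0
c3: 1000.0
c4: 0.2
c5: 0.5
c6: 0.201
c7: 0.0048
c8: 0.205
c9: 20.05
c10: 0.05
c11: 10.2
c12: 4.0
c13: 80.15
c14: 250.0
c15: 0.1
c16: 425.0
n1: 4.0
n2: 4.0
n3: 4.0
n4: 1.0
n5: 2.0
n6: 1.0
n7: 3.0
n8: 1.0
n9: 3.0
n10: 1.0
n11: 3.0
n12: 1.0
n13: 1.0
n14: 2.5
n15: 1.0
n16: 4.0
delta1: 0.169
delta2: 0.169
delta3: 0.171
delta4: 0.171
delta5: 0.1
# dorsoventral branch (Gli production scale deltaG, WcritG, h6 and k4 are
# published; the remaining constants follow the established minimal
# dorsoventral model, see docs/methods.md)
alpha: 3.0
beta: 5.0
gamma: 5.0
deltaG: 5.0
k1: 1.0
k2: 0.3
k3: 1.0
k4: 0.15
h1: 6.0
h2: 2.0
h3: 6.0
h4: 2.0
h5: 1.0
h6: 1.0
NcritP: 0.26
OcritP: 0.9
NcritO: 1.0
OcritN: 3.0
PcritN: 1.6
WcritG: 1.0
# morphogens
D_WNT: 150.7
D_SHH: 133.4
delta_WNT: 0.04
delta_SHH: 0.1
WNT_prod: 2.0
SHH_prod: 1.0
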