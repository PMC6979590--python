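# Consolidation of a loaded, top-drained unit column (60 hexahedral slabs).
label = "terzaghi"

[mesh]
generator = "box_hex"
n = [1, 1, 60]
lengths = [1.0, 1.0, 1.0]

[material]
E = 100.0         # Pa
nu = 0.25
phi0 = 0.9
k0 = 1e-5         # m^3 s / kg
upsilon = 2e-5

[time]
dt = 0.01         # s
T = 1.0           # s

[bc.dirichlet.x0]
components = [true, false, false]
[bc.dirichlet.x1]
components = [true, false, false]
[bc.dirichlet.y0]
components = [false, true, false]
[bc.dirichlet.y1]
components = [false, true, false]
[bc.dirichlet.z0]
components = [false, false, true]

[bc.traction.z1]
normal = -1.0     # downward load p0 on the drained top

[bc.pressure.z1]
p = 0.0

[bc.flux.z0]
q = 0.0
[bc.flux.x0]
q = 0.0
[bc.flux.x1]
q = 0.0
[bc.flux.y0]
q = 0.0
[bc.flux.y1]
q = 0.0
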