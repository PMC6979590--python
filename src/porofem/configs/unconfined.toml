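# Unconfined compression of a poroelastic cylinder between smooth
# impermeable platens (reference parameter table of the stress-relaxation
# test problem). All quantities SI.
label = "unconfined"

[mesh]
generator = "cylinder_tet"
radius = 1.0
height = 1.0
target_cells = 3080

[material]
E = 1000.0        # Pa
nu = 0.15
phi0 = 0.9
k0 = 1e-3         # m^3 s / kg
upsilon = 1e-3

[time]
dt = 4.0          # s
T = 1000.0        # s

[bc.dirichlet.top]
components = [false, false, true]
value = [0.0, 0.0, -0.01]

[bc.dirichlet.bottom]
components = [false, false, true]
value = [0.0, 0.0, 0.0]

[bc.dirichlet.axis]
components = [true, true, false]
value = [0.0, 0.0, 0.0]

[bc.dirichlet.y0_plane]
components = [false, true, false]
value = [0.0, 0.0, 0.0]

[bc.flux.top]
q = 0.0

[bc.flux.bottom]
q = 0.0

[bc.pressure.lateral]
p = 0.0
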