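# Pressure-driven swelling of a unit cube with an embedded
# low-permeability octant (512 hexahedral elements).
label = "swelling"

[mesh]
generator = "box_hex"
n = [8, 8, 8]
lengths = [1.0, 1.0, 1.0]

[material]
E = 8000.0        # Pa
nu = 0.3
phi0 = 0.9
k0 = 1e-5         # m^3 s / kg
upsilon = 1e-4

[time]
dt = 0.02         # s
T = 20.0          # s

[bc.dirichlet.x0]
components = [true, false, false]
[bc.dirichlet.y0]
components = [false, true, false]
[bc.dirichlet.z0]
components = [false, false, true]

# inlet ramp 1e4 (1 - exp(-t^2/0.25)) Pa is applied by the swelling driver;
# the static config pins the outlet level
[bc.pressure.x1]
p = 0.0

[bc.flux.y0]
q = 0.0
[bc.flux.y1]
q = 0.0
[bc.flux.z0]
q = 0.0
[bc.flux.z1]
q = 0.0
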