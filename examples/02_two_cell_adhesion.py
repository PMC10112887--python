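"""Cell–cell adhesion versus repulsion on a two-cell fixture.

Runs the `two_cell_adhesion` scenario twice — once with cell–cell
adhesion switched on and once without — and prints the final phase-field
overlap Int phi_0^2 phi_1^2 and separation.  Adhesion (omega_cc > 0)
holds the pair in contact; without it, repulsion pushes the cells apart.
"""

from dataclasses import replace

from extrudesim.dynamics import run_simulation
from extrudesim.io import make_scenario
from extrudesim.lattice import center_of_mass
from extrudesim.topology import overlap_integral

for label, omega_cc, kappa_cc in [("adhesive", 0.003, 0.05), ("repulsive", 0.0, 0.05)]:
    sc = make_scenario("two_cell_adhesion", seed=1)
    params = replace(sc.config.energy_params(), omega_cc=omega_cc, kappa_cc=kappa_cc)
    result = run_simulation(
        sc.state, params, sc.config.dynamics_params(), snapshot_every=400
    )
    state = result.final_state
    overlap = overlap_integral(state.cells[0], state.cells[1], state.lattice)
    dx = abs(
        center_of_mass(state.cells[1], state.lattice)[0]
        - center_of_mass(state.cells[0], state.lattice)[0]
    )
    print(f"{label:9s}: overlap integral = {overlap:7.3f}   separation = {dx:5.2f}")

print(
    "\nThe adhesive pair keeps a large interface overlap at short separation;"
    "\nwith omega_cc = 0 the contact shrinks as repulsion dominates."
)
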