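"""Conceptual perturbations of the optimal helix conformation.

Runs compact versions of the four perturbation simulations and prints
how the optimal (rho, theta) responds: side-chain bulk near the
backbone squeezes both coordinates down; bulk held far away only acts
beyond a critical radius (~6 A) and then shrinks rho; a cylindrical
electric field steers theta; a radial stretch force steers rho.
"""

from turntilt import sweep_simulation

for kind, values, note in [
    ("near-bulk", (3.5, 6.5, 9.5), "theta and rho both decrease"),
    ("far-bulk", (3.5, 6.0, 9.5), "inert below sigma ~ 6 A, rho drops above"),
    ("electric", (-2.0, 0.0, 2.0), "theta follows the field sign"),
    ("stretch", (-4.0, 0.0, 4.0), "rho follows the force sign"),
]:
    df = sweep_simulation(kind, values)
    print(f"{kind}  ({note})")
    for row in df.itertuples(index=False):
        print(f"  parameter {row.parameter:+5.1f} -> "
              f"rho = {row.rho:.3f} Res/Turn, theta = {row.theta:6.2f} deg")
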