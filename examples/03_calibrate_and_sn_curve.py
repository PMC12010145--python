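"""Calibrate the damage parameters to reference lifetimes and rebuild the S-N curve.

The damage threshold r_d and the time-scale product eta_d*omega are
under-determined by the printed material table (the literal values give
lifetimes of tens of cycles), so they are fitted to the two extreme reference
simulated lifetimes (350 and 600 MPa); the amplitudes in between are genuine
predictions of the calibrated model.
"""

import math

from fatiguesim import MaterialParams, basquin_fit, build_bar_mesh, hourglass_profile
from fatiguesim.sn import TI64_REFERENCE_LIFETIMES, calibrate_damage_parameters, run_sn_sweep

mesh = build_bar_mesh(hourglass_profile(), 64)
anchors = [(350.0, TI64_REFERENCE_LIFETIMES[350.0]), (600.0, TI64_REFERENCE_LIFETIMES[600.0])]

result = calibrate_damage_parameters(anchors, engine="specimen", mesh=mesh)
print(f"calibrated r_d        = {result.r_d:.5g} Pa "
      f"(endurance threshold; {result.r_d / result.stall_threshold:.3f} of the virgin "
      f"driving force at 350 MPa)")
print(f"calibrated eta_d*omega = {result.eta_d_omega:.5g} Pa*cycles")
print(f"anchor residuals (log10-life): "
      + ", ".join(f"{k:.0f} MPa: {v:+.2e}" for k, v in result.residuals_log10.items()))

params = result.params(MaterialParams())
records = run_sn_sweep([350, 400, 450, 500, 550, 600, 650], engine="specimen", params=params, mesh=mesh)
print("\n  sigma_a [MPa]    N_f [cycles]    solver steps    reference")
for r in records:
    ref = TI64_REFERENCE_LIFETIMES.get(r.sigma_a)
    note = f"{ref:12.0f}" if ref else "           -"
    print(f"  {r.sigma_a:12.0f}    {r.n_f:12.1f}    {r.solver_steps:12d}    {note}")

fit = basquin_fit(records)
print(f"\nBasquin fit: sigma_a = {fit.coefficient:.1f} * N_f^{fit.exponent:.4f}  (r^2 = {fit.r_squared:.4f})")
print("Anchors (350/600 MPa) are reproduced to ~1e-6 in log10-life; the held-out")
print("400/450 MPa lifetimes come out within an order of magnitude of the reference")
print("values - the single-threshold model bends the knee of the curve less sharply.")
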