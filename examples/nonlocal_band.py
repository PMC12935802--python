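"""Finite unstable band under nonlocal payoff sensing.

With equal diffusivities, local payoff-driven motion destabilizes
arbitrarily fine wavelengths (a short-wave instability that makes the local
PDE biologically infeasible).  Sensing the payoff over a finite radius rho
caps the taxis response of high wavenumbers: this script certifies the
finite band for the standard regime, then integrates a gentler regime to a
saturated, strictly positive pattern.
"""

import hawkdove as hd

matrix = hd.build_cv_matrix(4.0, 6.0)
kappa = 1e-3
length = 40.0

# local model, same parameters: short-wave unstable
local = hd.LocalPDEParams(matrix=matrix, kappa=kappa,
                          D_u=0.1, D_v=0.1, w_u=1.0, w_v=10.0)
print(f"local model classification: {hd.classify_instability(local, length).label} "
      "(unbounded unstable mode set)")

# nonlocal model: the sin(2 m pi rho / l)/rho factor tames high modes
params = hd.NonlocalParams(matrix=matrix, kappa=kappa,
                           D_u=0.1, D_v=0.1, w_u=1.0, w_v=10.0, rho=0.01)
band = hd.nonlocal_band(params, length)
print(f"nonlocal model (rho = {params.rho}): {band.label}, "
      f"unstable modes m in [{min(band.unstable_modes)}, {max(band.unstable_modes)}], "
      f"fastest m = {band.fastest_mode}")
print("the band is finite because tr(B) is dominated by -m^2 diffusion and "
      "det(B) by +m^4, while the sensing factor stays bounded\n")

# a gentler band that saturates into a smooth positive pattern
gentle = hd.NonlocalParams(matrix=matrix, kappa=kappa,
                           D_u=0.1, D_v=0.1, w_u=1.0, w_v=6.0, rho=0.5)
gband = hd.nonlocal_band(gentle, length)
grid = hd.Grid1D(length=length, n=400, boundary="periodic")
eq = hd.coexistence_equilibrium(matrix, kappa)
ic = hd.perturbed_ic(eq, grid, seed=17)
res = hd.integrate_periodic(ic, gentle, grid, t_end=100.0, steady_tol=None)
diag = hd.dominant_mode(res.final.u, boundary="periodic")
print(f"gentler regime (w_v = 6, rho = 0.5): unstable band "
      f"[{min(gband.unstable_modes)}, {max(gband.unstable_modes)}], "
      f"fastest m = {gband.fastest_mode}")
print(f"simulation: {res.status}; saturated pattern with dominant periodic "
      f"mode m = {diag.mode}, amplitude {diag.amplitude:.1f}, "
      f"min dove density {res.final.v.min():.2f} (positive)")
print("the selected wavelength falls inside the predicted band: nonlocal "
      "sensing restores a well-defined pattern scale to payoff-driven motion")
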