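"""Fit hyperbolic uptake-biomass phase relations for N, P and K.

With time eliminated, uptake tracks biomass along N_u = N_um*Y/(K_y + Y).
The relation linearizes to Y/N_u = K_y/N_um + Y/N_um, fitted by OLS; plant
nutrient concentration N_c = N_um/(K_y + Y) then falls with yield — the
nutrient dilution curve.
"""

from growthquant import concentration_predict, fit_phase, load_fixture

ala = load_fixture("alabama_trajectory").measured

for element in ("N", "P", "K"):
    pairs = list(zip(ala["Y_total"], ala[f"{element}u"]))
    fit = fit_phase(pairs, element=element)
    print(f"{element}: N_um = {fit.N_um:6.1f} kg/ha  K_y = {fit.K_y:5.2f} Mg/ha"
          f"  (linearized r = {fit.diagnostics.r:.4f}, n = {fit.diagnostics.n})")
    if element == "N":
        nc0 = concentration_predict(0.35, fit)
        nc_end = concentration_predict(7.8, fit)
        print(f"   plant N concentration falls {nc0:.1f} -> {nc_end:.1f} g/kg"
              " across the season (dilution with growth)")
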