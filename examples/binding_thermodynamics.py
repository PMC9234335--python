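"""Van't Hoff analysis: binding constants at three temperatures to
dH, dS, dG and the dominant intermolecular force.

ln K_a vs 1/T is linear when dH is constant over the window; the slope
gives -dH/R and the intercept dS/R.  The signs of dH and dS identify the
force: both negative means van der Waals contacts and hydrogen bonds
dominate.
"""

from specbind import gibbs, ka_from_thermo, vant_hoff_fit

# exothermic binding with an entropy penalty, K_a(298) = 2e4 L/mol
truth_dh, truth_ds = -30.0, -18.33
ka_by_temperature = {t: ka_from_thermo(truth_dh, truth_ds, t)
                     for t in (288.0, 298.0, 308.0)}
for t, ka in ka_by_temperature.items():
    print(f"T = {t:.0f} K:  K_a = {ka:.3e} L/mol")

params = vant_hoff_fit(ka_by_temperature)
print(f"\ndH = {params.dh:+.2f} kJ/mol   (heat released on binding)")
print(f"dS = {params.ds:+.2f} J/(mol K) (order imposed on the complex)")
for t, dg in sorted(params.dg_at.items()):
    print(f"dG({t:.0f} K) = {dg:+.2f} kJ/mol")
print(f"force class: {params.force_class}")
print(f"\ncheck: dG(298) from dH - T dS = {gibbs(params.dh, params.ds, 298.0):+.2f} kJ/mol")
print("negative dG -> spontaneous binding; dH<0 and dS<0 -> van der Waals + H-bonds.")
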