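"""Estimating the electrical depth of the binding site.

Two routes to delta_b for the NMDA-receptor block: the exact closed-form
inversion from two published voltage points, and a weighted least-squares
fit of a synthetic full voltage curve.
"""

import azoblock as az
from azoblock.fitting import fit_voltage_curve, two_point_delta

thermo = az.ThermoContext(296.0)

# exact two-point inversion of the published mean ratios (30 uM, NMDA)
d_qaq, kbc_qaq = two_point_delta(0.26, -120.0, 0.62, -20.0, z=2, thermo=thermo)
d_aaq, kbc_aaq = two_point_delta(0.31, -120.0, 0.46, -20.0, z=1, thermo=thermo)
print(f"two-point delta_b:  QAQ {d_qaq:.3f}   AAQ {d_aaq:.3f}")
print(f"mean {0.5 * (d_qaq + d_aaq):.3f}  (consensus fitted value: 0.18)")
print(f"implied K_b:        QAQ {kbc_qaq * 30:.1f} uM  AAQ {kbc_aaq * 30:.1f} uM")

# full-curve fit on a synthetic dataset at the study conditions
cfg = az.GeneratorConfig(preset="QAQ/NMDA/dark", seed=42, n_cells=6, noise_sd=0.05)
gen = az.gen_voltage_dataset(cfg)
res = fit_voltage_curve(gen.summary, model="eq1", z=2, seed=0)
print(f"\nfitted on synthetic voltage curve (n = 6 cells, noise SD 0.05):")
print(f"  delta_b = {res.estimates['delta_b']:.3f} "
      f"(generating value {az.preset('QAQ/NMDA/dark', kind='block').block.delta_b})")
print(f"  K_b     = {res.estimates['K_b']:.1f} uM "
      f"(generating value {az.preset('QAQ/NMDA/dark', kind='block').block.K_b:.1f})")
print(f"  weighted SSR = {res.objective:.4f}, AICc = {res.aicc:.1f}")
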