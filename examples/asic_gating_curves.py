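"""Steady-state gating of the two native ASIC1a models.

Builds the homomeric and heteromeric channel parameter sets, evaluates
their pH-dependent activation/inactivation curves and inactivation time
constants, and prints the landmarks that characterize each variant.
"""

from scipy.optimize import brentq

from windup_asic.asic import ASICParams, h_inf, m_inf, peak_product_pH, tau_h

for variant in ("homomeric", "heteromeric"):
    p = ASICParams.from_variant(variant)
    ph_m = brentq(lambda x: m_inf(x, p) - 0.5, 5, 8)
    ph_h = brentq(lambda x: h_inf(x, p) - p.alpha / 2, 5, 9)
    print(f"{variant:12s} pH0.5(activation) = {ph_m:.2f}   "
          f"pH0.5(inactivation) = {ph_h:.2f}   h ceiling = {p.alpha}")
    print(f"{'':12s} peak window-current pH = {peak_product_pH(p):.3f}   "
          f"tau_h at that pH = {tau_h(peak_product_pH(p), p):.1f} s")

# The window between the activation and inactivation midpoints is where a
# sustained acid shift opens a steady fraction of channels; its peak pH is
# the acidity at which the synaptically driven ASIC current is largest.
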