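"""The bell-shaped contribution of ASIC1a conductance to windup.

Sweeps the per-synapse homomeric ASIC conductance and prints the windup
AUC: moderate conductances potentiate windup, high conductances suppress
it through calcium-activated potassium channels, and removing the ASIC
calcium fraction removes the suppression.
"""

from dataclasses import replace

from windup_asic.engine import ScenarioConfig, conductance_sweep, run_windup

base = ScenarioConfig()
tab = conductance_sweep("homomeric", [0.0, 0.05, 0.2, 1.0, 1.4], base)
for _, row in tab.iterrows():
    print(f"g = {row.g_asic_nS:4.2f} nS   AUC = {row.auc:5.1f}   "
          f"total = {row.total:4.0f}")

noca = run_windup(replace(base, asic_variant="homomeric", g_asic=1.4,
                          ca_fraction=0.0)).windup()
print(f"g = 1.40 nS, calcium-free ASIC: AUC = {noca.auc:5.1f}  "
      "(the high-conductance suppression is calcium-dependent)")
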