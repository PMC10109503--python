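"""MitTx-locked channels and KCa block.

MitTx locks ASIC channels fully open independent of pH; at the same
0.2 nS conductance where dynamically gated channels potentiate windup,
the locked channel's sustained calcium load recruits KCa and abolishes
windup.  Blocking KCa (apamin + iberiotoxin scenario) rescues the
suppression seen at a high ASIC conductance.
"""

from windup_asic.engine import ScenarioConfig, run_windup

ctrl = run_windup(ScenarioConfig()).windup()
dyn = run_windup(ScenarioConfig(asic_variant="homomeric", g_asic=0.2)).windup()
mtx = run_windup(ScenarioConfig(asic_variant="homomeric", g_asic=0.2,
                                mittx=True)).windup()
hi = run_windup(ScenarioConfig(asic_variant="homomeric", g_asic=1.4)).windup()
resc = run_windup(ScenarioConfig(asic_variant="homomeric", g_asic=1.4,
                                 kca_scale=0.0)).windup()
print(f"control AUC             = {ctrl.auc:6.1f}")
print(f"dynamic ASIC 0.2 nS     = {dyn.auc:6.1f}   (potentiation)")
print(f"MitTx-locked 0.2 nS     = {mtx.auc:6.1f}   (suppression)")
print(f"dynamic ASIC 1.4 nS     = {hi.auc:6.1f}   (suppression)")
print(f"1.4 nS + KCa blocked    = {resc.auc:6.1f}   (rescue)")
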