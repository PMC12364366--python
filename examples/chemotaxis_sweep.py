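"""How chemotaxis strength shapes cell migration.

Sweeps the chemotaxis constant k on the steep Gaussian-stimulus
scenario (400 resident macrophages), recording the cumulative number of
chemotactic moves N_c in a 36-hour run per k, and fits the power law
N_c ~ A * k^m on the k > 0 points.
"""

from mff import builtin_scenario, fit_power_law, run

ks = [0.0, 0.02, 0.5, 1.0, 2.0]
ncs = []
for k in ks:
    cfg = builtin_scenario("chemotaxis_sweep")
    cfg.duration_h = 36.0
    cfg.params.k_chemo = k
    trace = run(cfg, seed=5)
    ncs.append(float(trace.data["n_c"].iloc[-1]))
    print(f"k={k:4.2f}  N_c={ncs[-1]:7.0f}")

fit = fit_power_law(ks, ncs)
print(f"\nfit on k>0 points: N_c ~ {fit.A:.0f} * k^{fit.m:.3f} "
      f"(+/- {fit.m_se:.3f})")
print("N_c counts every cell move driven by the PIM gradient; it is 0 "
      "with chemotaxis off\nand grows sub-linearly with k because "
      "steep-gradient moves saturate at probability 1.")
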