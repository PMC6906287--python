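"""Population-level inference on a simulated event cohort.

Fits the censored-exponential docking lag and the Gaussian flow-rate
distribution, then splits flow rates at the 70 nm diameter cutoff for a
mechanosensitive (protein-pore-like) run and reports the KS comparison.
"""

from poretrace import experiments as E
from poretrace.popstats import fit_exponential_lag, fit_gaussian_rates

dock = E.docking_lag_recovery(seed=42)
print(f"docking lag: censored MLE {dock['estimate_s']:.0f} s from "
      f"{dock['n_events']} events + {dock['n_censored']} censored "
      f"(true {dock['true_s']:.0f} s)")

flow = E.flow_rate_recovery(seed=42)
print(f"flow rate:   Gaussian fit {flow['mean_estimate']:.4f} /s "
      f"(configured {flow['true_mean']}) over {flow['n_events']} events")

power = E.mechano_power(seed=42)
print(f"mechanosensitivity: large/small flow-rate ratio "
      f"{power['rate_ratio']:.2f}, KS D = {power['ks_statistic']:.3f}, "
      f"p = {power['ks_pvalue']:.2e} "
      f"({power['n_small']}/{power['n_large']} events per side)")
print("A mechanosensitive pore shows faster flux in large (low-curvature) "
      "vesicles; the KS test on the 70 nm split detects it, while "
      "mechano-insensitive runs reject at the nominal 5% rate.")
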