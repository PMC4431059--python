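"""Base-case cost-effectiveness of immediate vs. delayed ranibizumab.

Simulates 10,000 patients through each treatment arm over the 2-year
horizon and prints per-arm mean costs and QALYs, the increments, and the
ICER, alongside the deterministic cohort expectation (the model's exact
answer, free of Monte Carlo noise).
"""

from amdcea import StrategyConfig, cohort_expectation, icer, load_parameters, run_arm

params = load_parameters()
N, SEED = 10_000, 1

results = {}
for arm in ("delayed", "immediate"):
    res = run_arm(StrategyConfig(arm), params, N, seed=SEED)
    exact = cohort_expectation(StrategyConfig(arm), params)
    results[arm] = res
    print(f"{arm:>9} arm: cost £{res.mean_cost:8.2f} (±{res.se_cost:.2f})  "
          f"QALYs {res.mean_qaly:.3f} (±{res.se_qaly:.4f})  "
          f"injections {res.mean_injections:.2f}   "
          f"[expectation: £{exact['mean_cost']:.2f}, {exact['mean_qaly']:.3f} QALYs]")

dc = results["immediate"].mean_cost - results["delayed"].mean_cost
de = results["immediate"].mean_qaly - results["delayed"].mean_qaly
print(f"\nincremental: £{dc:.2f} for {de:.3f} QALYs -> ICER {icer(dc, de)}")
print("Immediate treatment keeps more patients in the best vision band, so it")
print("gains QALYs at extra injection cost. Note the delayed arm here runs on")
print("a documented stand-in for the unpublished fellow-eye decline curve, so")
print("its absolute results (and hence the ICER) are illustrative only; the")
print("immediate-arm results derive entirely from published inputs.")
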