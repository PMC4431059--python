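# amdcea

Patient-level Markov cost-effectiveness model of **immediate vs. delayed
ranibizumab** treatment in neovascular age-related macular degeneration
(nAMD), for health economists and modellers who want a tested, scriptable
implementation of the full pipeline: parameterisation from visit records,
microsimulation, one-way scenarios, and probabilistic sensitivity
analysis.

## The model

Patients move monthly between five visual-acuity bands
*s ∈ {6/6–>6/12, 6/12–6/24, 6/24–6/60, 6/60–3/60, <3/60}* plus absorbing
death, starting with a single 3-month loading cycle. Each cycle accrues

```
QALYs += u(s) · Δt/12        cost += c_drug + c_assess   (injection months)
                             cost += c_monitor            (monitoring months)
```

with utilities *u(s)* from time trade-off elicitation (0.89 … 0.40),
2012 NHS unit costs (£742.17 / £255.00 / £60.00), and gender-specific
background mortality *q(age)* applied before each transition. The
immediate arm starts treatment at once; the delayed arm waits in the
best band until vision drops below 6/12 (exponential drop time, median
6 months — a documented stand-in for the unpublished fellow-eye curve),
re-enters in a worse band, then starts treatment. Strategies are
compared by ΔC, ΔE, the ICER ΔC/ΔE, and net monetary benefit
λ·ΔE − ΔC; parameter uncertainty is propagated with beta (utilities),
gamma (costs) and Dirichlet (transition rows) draws into a
cost-effectiveness plane and acceptability curve (CEAC).

A deterministic cohort-expectation oracle mirrors the simulation
exactly (state-occupancy propagation, age-mixture integration) and the
test suite requires Monte Carlo/oracle agreement, probability
conservation, and parameter recovery from synthetic visit records.

## Worked example

```python
from amdcea import StrategyConfig, load_parameters, run_arm, icer

params = load_parameters()                     # packaged base case
imm = run_arm(StrategyConfig("immediate"), params, 10_000, seed=1)
del_ = run_arm(StrategyConfig("delayed"), params, 10_000, seed=1)
print(imm.mean_qaly, imm.mean_cost)
print(icer(imm.mean_cost - del_.mean_cost, imm.mean_qaly - del_.mean_qaly))
```

Running `python examples/01_base_case.py` prints:

```
  delayed arm: cost £ 6180.36 (±30.83)  QALYs 1.504 (±0.0036)  injections 5.63   [expectation: £6153.71, 1.504 QALYs]
immediate arm: cost £ 8472.52 (±24.11)  QALYs 1.565 (±0.0037)  injections 7.61   [expectation: £8461.72, 1.567 QALYs]

incremental: £2292.16 for 0.061 QALYs -> ICER 37617.14 (ratio)
```

The immediate arm accrues ~1.57 QALYs and ~£8,470 over two years —
these rest entirely on published inputs. The delayed arm runs on the
stand-in drop curve, so its absolute results (and hence the increments
and ICER) are illustrative of the mechanism rather than reproductions;
see `docs/methods.md` for why the published delayed-arm decline is not
recoverable from printed inputs.

The other example scripts cover the PSA/CEAC
(`examples/02_psa_ceac.py`), one-way scenarios
(`examples/03_one_way_scenarios.py`), and estimator validation by
parameter recovery (`examples/04_synthetic_emr_recovery.py`).

## Command line

The same runs are available from a shell, each writing seed-stamped
CSVs:

```
amdcea base-case --n-patients 10000 --seed 1 --out-dir results
amdcea psa --n-iterations 1000 --seed 1 --out-dir results
amdcea scenarios --seed 1 --out-dir results
amdcea generate-emr --n-patients 5000 --out-dir results
amdcea estimate-params results/visits.csv --out-dir results
amdcea recover --n-patients 5000 --out-dir results
```

## Layout

```
src/amdcea/       params · simulation · economics · psa · synthetic_emr · cli
src/amdcea/data/  base_case.yaml (all base-case inputs, validated at load)
examples/         narrative scripts, one per capability
tests/            unit, property and end-to-end acceptance tests
docs/methods.md   modelling conventions, parameter provenance, limitations
```
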