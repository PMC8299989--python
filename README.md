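# glottiflow

Reduced-order modelling of glottal airflow for voice-production research.

During phonation, air driven by the subglottal pressure interacts with the
vocal folds; the shape of the glottis (the airspace between the folds)
alternates between convergent and divergent within each vibration cycle, and
in pathological voicing it can be curved or split into multiple channels.
Full Navier–Stokes simulation of these flows is accurate but far too slow
for clinical use; the classical Bernoulli description is fast but inviscid
and often badly wrong. `glottiflow` implements the middle ground: a
quasi-1D modified Bernoulli model whose per-segment viscous loss is
predicted by a small neural network trained on reference section data, plus
everything needed to exercise it — a kinematic vocal-fold shape generator, a
deterministic ground-truth surrogate, training/evaluation pipelines, and a
simplified fluid–structure interaction (FSI) loop that produces
self-sustained oscillation.

It is aimed at voice/biomechanics researchers who want a fast, differentiable
-in-spirit surrogate of glottal aerodynamics and a fully reproducible
training pipeline to retarget it at their own reference data.

## The model

With `n + 1` uniform cross sections of area `A_i` from the contraction entry
(area `A_s`) to the glottal exit (`A_n`), and supraglottal area `A_c`:

    P_s + ρ/2 (Q/A_s)² = P_n + ρ/2 (Q/A_n)² + ρ/2 Q² Σ_{i=1..n} f_ri / A_i²
    P_n − P_c = −ρ/2 (Q/A_n)² · 2 (A_n/A_c)(1 − A_n/A_c)

so the flow rate has the closed form

    Q = sqrt( 2(P_s−P_c)/ρ / [ −1/A_s² + (1 − 2(A_n/A_c)(1−A_n/A_c))/A_n²
                               + Σ f_ri/A_i² ] ).

Each dimensionless resistance `f_ri` is predicted from eight per-section
features (normalized position, area and hydraulic diameter, upstream and
downstream diameter slopes, shape change rate, pressure-drop coefficient,
Reynolds number) by a fully connected network (256/64/16/4 hidden units,
ReLU, 20 % dropout, Nadam, L2 penalty). Because the features depend on `Q`
and `Q` on `f_r`, prediction iterates the two to a fixed point. Training
targets come from inverting the same pressure balance on reference section
data — externally supplied tables, or the package's deterministic viscous
surrogate. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from glottiflow import (FluidProperties, FlowConditions, default_shape_set,
                        discretize_channel, build_training_set, solve_flow_rate,
                        pressure_distribution, solve_self_consistent,
                        relative_errors, summarize_errors)
from glottiflow.dnn import DNNConfig, split_data, train_final, evaluate_mae
from glottiflow.oracle import make_ground_truth

fluid, cond = FluidProperties(), FlowConditions()   # air, 1 kPa -> 0 kPa

channels = default_shape_set()                       # 64 synthetic shapes
records = build_training_set(channels, fluid, cond)  # 8192 (features, fr) rows
train, test = split_data(records, 0.2, seed=0)
model = train_final(train, DNNConfig(epochs=2000, seed=0))
mae, rel = evaluate_mae(model, test)
print(f"held-out MAE {mae:.3f}  (relative {100*rel:.1f}%)")

rep_plain, rep_learned = [], []
for sid in sorted(test["shape_id"].unique()):
    shape = discretize_channel(channels[int(sid)], 128)
    truth = make_ground_truth(shape, fluid, cond)
    ref = pressure_distribution(shape, np.zeros(shape.n), fluid, cond, truth.Q_ref)
    ref.pressures_P, ref.Q = truth.mean_pressures, truth.Q_ref
    qb = solve_flow_rate(shape, np.zeros(shape.n), fluid, cond)
    plain = pressure_distribution(shape, np.zeros(shape.n), fluid, cond, qb)
    learned = solve_self_consistent(shape, fluid, cond, model)
    rep_plain.append(relative_errors(ref, plain, cond))
    rep_learned.append(relative_errors(ref, learned, cond))
for name, s in [("plain Bernoulli", summarize_errors(rep_plain)),
                ("learned (DNN)  ", summarize_errors(rep_learned))]:
    print(f"{name}: E_Q max {s['E_Q_max']:8.1f} mean {s['E_Q_mean']:7.1f}   "
          f"E_P max {s['E_P_max']:6.1f} mean {s['E_P_mean']:5.1f}")
```

prints (seed 0)

```
held-out MAE 2.642  (relative 19.4%)
plain Bernoulli: E_Q max  15674.5 mean  5246.2   E_P max 1717.4 mean 244.0
learned (DNN)  : E_Q max     78.4 mean    37.7   E_P max    4.2 mean   1.5
```

The errors are percentages against the surrogate ground truth on the 13
held-out shapes. The inviscid model is off by orders of magnitude on
nearly-closed divergent shapes where the surrogate's separation losses are
deliberately harsh (see `docs/methods.md`); the learned resistance brings
both flow-rate and pressure errors down by two orders of magnitude. The
relative MAE plateaus near 16–19 % with the default 20 % dropout — the
no-dropout capacity of the same architecture on this corpus is ~3.5 % —
which is discussed in the methods note.

The same workflows are scriptable from the shell:

```bash
glottiflow pipeline --fast --seed 1 --out runs/demo     # Figs-style end-to-end
glottiflow shapes --fast --mesh-format stl --out runs/shapes
glottiflow solve --fast --shape-index 3
```

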