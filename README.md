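# hhesn — hybrid reservoir / Hodgkin-Huxley model-error correction

`hhesn` builds and benchmarks hybrid systems that couple an echo-state
reservoir to an approximate ("surrogate") Hodgkin-Huxley neuron model in
order to correct the surrogate's model error: given only the membrane
voltage V(t) and the driving current I(t) of a reference neuron, the hybrid
is trained to predict the corrected voltage in closed loop — and, because
the surrogate's gate variables run freely inside the loop, it also
reconstructs the unobservable ion-gate dynamics m(t), h(t), n(t).

It is aimed at computational neuroscientists and dynamical-systems
researchers who fit conductance-based models to voltage recordings and need
to know how far a wrong model can be pushed back toward the truth by a
trained recurrent network.

## The model

The neuron is a conductance-based point model,

    C dV/dt = g_Na m³h (E_Na − V) + g_K n⁴ (E_K − V) + g_L (E_L − V) + I(t)
    dχ/dt   = (χ∞(V) − χ)/τ_χ(V),    χ ∈ {m, h, n}

with sigmoidal steady states χ∞(V) = ½(1 + tanh[(V − V_χ)/dV_χ]) and
bell-shaped relaxation times τ_χ(V) = τ0_χ + ε_χ(1 − tanh²[(V − V_χ)/dVt_χ]).
Model error is introduced by fractionally detuning the sodium parameters:
g_Na → g_Na(1+ε_g), V_m → V_m(1+ε_V), τ_m → τ_m(1+ε_τ).

The reservoir is a sparse symmetric random graph of tanh nodes,
r(t+Δt) = tanh[A r(t) + W_in v_in(t)], with a 0/1 block input layer and a
ridge-regressed linear readout Ṽ = W_out r + w_out (Tikhonov constant β,
mean-matching bias).  Six hybrid variants couple the surrogate to the
reservoir: the model passes either V only (TVH) or all of V, m, h, n (ASVH)
into the input layer (IH), the readout (OH), or both (FH); a fraction γ of
the nodes listens to the model channels.  Training is teacher-forced on
(V(t), I(t)) sampled at Δt = 25 µs; prediction feeds the readout voltage
back in place of the measurement.

Training currents mix chaotic Lorenz segments with random-amplitude step
trains, switched at random times, so that the drive probes all gate
kinetics (the package includes a spectral coverage diagnostic).

## Worked example

Train the best-performing hybrid (ASVH-FH, γ = 0.5) against a surrogate
whose sodium conductance is 10 % off, on the default desk-scale benchmark
(312.5 ms training window, 2500 ms held-out prediction window, 300-node
reservoir, published hyperparameters):

```python
from hhesn.benchmark import BenchmarkConfig, make_benchmark_data, run_case
from hhesn.neuron import ModelError

config = BenchmarkConfig()          # 312.5 ms training, 2500 ms prediction, 300 nodes
data = make_benchmark_data(config, seed=0)
err = ModelError(eps_g=0.10)        # 10 % sodium-conductance error

surrogate = run_case(data, "surrogate", err)
hybrid = run_case(data, "asvh-fh", err)

print(f"raw surrogate  median RMSE: {surrogate.windowed.median:6.2f} mV")
print(f"ASVH-FH hybrid median RMSE: {hybrid.windowed.median:6.2f} mV")
for gate in ("m", "h", "n"):
    ratio = hybrid.gate_rmse[gate]["corrected_rmse"] / surrogate.gate_rmse[gate]["raw_rmse"]
    print(f"gate {gate}: corrected/raw hidden-state RMSE = {ratio:5.2f}")
```

prints

```
raw surrogate  median RMSE:  17.76 mV
ASVH-FH hybrid median RMSE:   4.29 mV
gate m: corrected/raw hidden-state RMSE =  0.23
gate h: corrected/raw hidden-state RMSE =  0.17
gate n: corrected/raw hidden-state RMSE =  0.16
```

The hybrid cuts the voltage prediction error of the detuned model by a
factor of four over a held-out current protocol, and pulls the hidden gate
trajectories 4–6× closer to the reference — state variables it was never
trained on, since only the voltage is observable.

There is also a CLI for file-based pipelines:

```bash
hhesn generate --outdir runs/demo          # protocols + reference trajectory
hhesn train --outdir runs/demo --mode hybrid --variant asvh-fh --eps-g 0.1
hhesn predict --system runs/demo/system_hybrid.npz \
              --protocol runs/demo/predict_protocol.npz --out runs/demo/pred.tsv
hhesn sweep --outdir runs/demo --error-type eps_g
```

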