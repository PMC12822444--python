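# airtherm

Simulation and detection toolkit for **airflow-driven thermoelectric
physiological monitoring**. A wearable thermoelectric device (TED) mounted
over the airways sees alternating warm exhale and cool inhale airflow;
forced convection modulates the temperature difference across its p/n
semiconductor legs, and the Seebeck effect turns that into a voltage that
tracks respiration, speech airflow, and coughing. `airtherm` implements the
forward physics of that chain and the downstream recognition layer: a
cough-alarm rule, an airflow-speech classifier, and a multi-source
(respiration/speech + heartbeat) fusion classifier for emergency-state
detection, all exercised on seeded synthetic signals.

## Model

The convective coefficient for laminar flow over the flat device surface
follows the average-Nusselt correlation

```
h(v) = (κ/L)·Nu = 0.664 (κ/L) Re^{1/2} Pr^{1/3},   Re = ρ_air v L / μ
```

The fluid-contact surface obeys a lumped energy balance (Newton cooling)

```
m c_p dT_upper/dt = h(v) A (T_air − T_upper)   ⇒   dT_upper/dt = f(v)(T_air − T_upper)
```

with thermal rate `f = hA/(m c_p)`, whose constant-flow solution is the
exponential relaxation `T_upper(t) = T_air − (T_air − T_upper(0)) e^{−f t}`.
The output voltage is `V = α·ΔT_TED` with `ΔT_TED = T_upper − T_lower`
(α = α_p − α_n = 412.5 µV/K per couple for the Bi₂Te₃-family legs used).
A reduced 1-D steady-state leg solver (conduction + Joule source + Robin
convective boundary) reproduces the open-circuit and loaded behaviour of a
single thermocouple and its velocity-sweep trend.

## Worked example

Open-circuit velocity sweep of one p/n couple under 12 °C airflow with a
20 °C skin-side temperature:

```
$ airtherm sweep --steps 5
velocity_mps,dT_K,v_oc_V
1.0,-1.7388155591821715,-0.0007170564088636454
2.0,-2.255910590811908,-0.0009303191060884965
3.0,-2.5982191696422205,-0.0010715011149362496
4.0,-2.856614379276465,-0.001178076753424725
5.0,-3.06460671082084,-0.0012638654474386246
```

The cold airflow cools the fluid-contact end (negative ΔT), and both |ΔT|
and the open-circuit voltage magnitude grow monotonically with inlet speed
— at 5 m/s the couple develops ≈ −3.1 K across its legs and ≈ −1.26 mV.

Cough alarm on a synthetic severe-cough train:

```python
from airtherm import DevicePlate, FluidProperties, simulate_response
from airtherm.physio_synth import gen_cough_train
from airtherm.features_detect import detect_coughs, alarm_rule

plate, air = DevicePlate(), FluidProperties()
flow = gen_cough_train("severe", count=3, window=5.0, fs=100.0, seed=2)
trace = simulate_response(plate, air, flow, T_upper0=plate.T_lower)
events = detect_coughs(trace)
state = alarm_rule(events)
print([(round(e.time, 2), e.intensity) for e in events], state.active)
# [(0.65, 'severe'), (2.59, 'severe'), (3.94, 'severe')] True
```

Three severe coughs inside a 5 s window trigger the alarm (at t = 3.94 s,
the event completing the count); mild or moderate coughs never do.

Other entry points: `airtherm simulate` (airflow CSV → voltage-trace CSV),
`airtherm synth` (labeled fusion dataset + manifest), `airtherm
train-speech` / `train-fusion` (classifier reports as JSON), `airtherm run`
(full pipeline from a JSON config).

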