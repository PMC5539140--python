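"""Validating a model against steady-state chemostat growth.

At steady state in a chemostat the specific growth rate equals the dilution
rate D.  Clamping the model's substrate exchange to the measured uptake and
maximizing biomass yields a predicted growth rate; its relative error
against D measures model consistency.  Here a yield-1 chain fed at
0.042 mmol/gDCW/h against D = 0.039/h predicts 0.042/h — a 7.7% relative
error, i.e. the model slightly over-predicts growth for the measured uptake.
"""

from tagknock import make_chemostat_fixture, predict_chemostat_growth

model, condition, _ = make_chemostat_fixture(
    dilution_rate=0.039, yield_coefficient=1.0, uptake_rate=0.042
)
pred = predict_chemostat_growth(model, condition)
print(f"dilution rate D:        {pred.dilution_rate:.6f} /h")
print(f"predicted growth rate:  {pred.predicted_growth:.6f} /h")
print(f"relative error |mu-D|/D: {pred.relative_error:.6f}")
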