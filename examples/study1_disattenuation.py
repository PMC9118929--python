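"""Mini disattenuation benchmark: DA vs DQ reliability in the correction.

Two constructs with true correlation .7 are each measured by 10 items;
the sum-score correlation is corrected with reliabilities computed from
the true item parameters, analytically (DA) or by quadrature (DQ).
A fraction of the full design (one cell, 200 replications) to keep the
example fast.
"""

from dichrel import Study1Config, run_study1

cfg = Study1Config(correlations=(0.7,), items_per_construct=(10,), n_reps=200, seed=42)
df = run_study1(cfg)
print(df.to_string(index=False))
print(
    "\nThe raw sum-score correlation is attenuated far below .7; the DQ\n"
    "correction recovers the truth almost exactly, while the DA correction\n"
    "falls short because the analytic reliabilities are slightly too high."
)
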