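"""Agreement statistics on the bundled ten-complex benchmark.

The benchmark table carries experimental pk_d values (and the free energies
they convert to) for ten protein-ligand complexes, together with this model's
predicted binding energies and a comparison empirical scoring function's
predictions on the pk scale.  The example recomputes the correlation of each
method with experiment and the fitted regression line of the model.
"""

from fourbody import PairedObservations, evaluate_predictions, pearson_r, pk_to_free_energy
from fourbody.evaluation import load_benchmark_table

table = load_benchmark_table()
print(table.to_string(index=False))
print()

# check the tabulated dG_exp column against the pk_d column
for _, row in table.iterrows():
    assert abs(pk_to_free_energy(row.pk_exp) - row.dg_exp) < 1e-6

model = PairedObservations(table.dg_exp.to_numpy(), table.dg_model.to_numpy())
summary = evaluate_predictions(model)
print(f"model vs experiment:   r = {summary.r:.2f}, SE = {summary.se:.2f} kcal/mol, "
      f"fit y = {summary.slope:.2f}x {summary.intercept:+.2f}")

xscore = PairedObservations(table.pk_exp.to_numpy(), table.pk_xscore.to_numpy())
print(f"x-score vs experiment: r = {pearson_r(xscore):.2f}  (pk scale; r is "
      f"invariant under the affine pk -> dG conversion)")
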