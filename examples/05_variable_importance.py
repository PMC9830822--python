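"""Rank predictors of a fitted PLS model by |standardized coefficient|.

On the synthetic calibration trial the intake signal reaches the spectrum
through the urea bands (milk urea nitrogen tracks feed intake) and the
protein bands; milk yield enters directly as a covariate.
"""

from milknue import generate_trial, t1_like_config
from milknue.models import ModelSpec, fit_calibration, importance_rank
from milknue.pipeline import prepare_trial

t1, _ = prepare_trial(generate_trial(t1_like_config(seed=0)))

for trait, label in (("nue_pct", "NUE"), ("dmi_a_kg", "DMI_a")):
    model = fit_calibration(t1, ModelSpec("M2", "original", "pls", trait), seed=11)
    top = importance_rank(model).head(8)
    print(f"{label} (M2, original spectra, PLS, {model.n_lv} latent variables)")
    for _, row in top.iterrows():
        print(f"  {row.predictor:>10}  |b| = {row.score:.3f}")
    print()

print("Channel names are wavenumbers in cm^-1; high-ranking channels cluster")
print("at the planted absorption bands, and milk yield ranks high for NUE.")
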