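"""Predict live body mass for a handful of measured arthropods.

Builds a few records with varying completeness (with/without width, taxon,
region), runs the model-selection cascade against the builtin parameter
database, and prints the predicted mass with the model family used and any
warning flags.
"""

import allomass as am

db = am.load_default_parameters()

records = [
    # fully characterized temperate spider: top-ranked LWTR family applies
    am.MorphometricRecord("spider-1", body_length=5.2, body_width=2.1,
                          taxon="Araneae", region="temperate"),
    # no width: falls back to the taxon x region length-only family (LTR)
    am.MorphometricRecord("beetle-1", body_length=12.0,
                          taxon="Coleoptera", region="tropical"),
    # unknown taxon but width available: the all-taxa width family (LWR)
    am.MorphometricRecord("unknown-1", body_length=8.0, body_width=2.5,
                          region="tropical"),
    # length only: the universal length-only regression (L)
    am.MorphometricRecord("unknown-2", body_length=10.0),
    # taxon never sampled in this region: cascades with a fallback flag
    am.MorphometricRecord("roach-1", body_length=20.0, body_width=7.0,
                          taxon="Dictyoptera", region="temperate"),
]

print(f"{'id':<10} {'model':<6} {'mass (mg)':>10}  flags")
for rec in records:
    res = am.predict_mass(rec, db)
    print(f"{rec.individual_id:<10} {res.model_used:<6} {res.mass_pred:>10.2f}  "
          f"{';'.join(sorted(res.flags)) or '-'}")

# Each line shows the most informative applicable regression: mass is
# 10**(a + b_len*log10 L [+ b_wid*log10 W]) with published coefficients.
# 'fallback_model' marks a record whose taxon x region combination was never
# sampled, so a less specific equation had to be used.
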