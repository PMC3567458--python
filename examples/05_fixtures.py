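"""Generate the synthetic datasets the package uses to exercise itself.

Virtual subjects are sampled within the ranges spanned by the published
study populations; PK curves are simulated, noised and truncated at an
assay-like quantification limit.  Everything is deterministic per seed.
"""

from raasim.io import generate_fixtures

subjects = generate_fixtures("subjects", n=5, seed=0)
print("virtual subjects (uniform within published population ranges):")
print(subjects.round(4).to_string(index=False))

curves = generate_fixtures("pk_curves", n=1, seed=0)
print(f"\none noisy oral-Ena curve: {len(curves)} quantifiable samples")
print(curves.head(6).to_string(index=False))

targets = generate_fixtures("raas_targets", n=1, seed=0, noise_cv=0.0)
print("\nnoise-free steady-state target table (umol/L):")
print(targets.to_string(index=False))
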