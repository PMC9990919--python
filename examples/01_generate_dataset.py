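"""Generate a synthetic binary-choice dataset and inspect its structure.

The generator draws a complete participants x questions table from a
latent-trait model: each cell gets a 0/1 correctness indicator and a
0-100 confidence rating, with confidence coupled to the same latent
evidence that drives correctness.
"""

from crowdwise import GeneratorConfig, generate_dataset, write_dataset

config = GeneratorConfig(n_participants=150, n_questions=70, seed=42)
dataset = generate_dataset(config)

print(f"task: {dataset.task_name}")
print(f"shape: {dataset.n_participants} participants x {dataset.n_questions} questions")
print(f"mean accuracy: {dataset.correct.to_numpy().mean():.3f}")
print(f"mean confidence: {dataset.confidence.to_numpy().mean():.1f}")

write_dataset(dataset, "synthetic_dataset.csv")
print("wrote synthetic_dataset.csv (long format, one row per cell)")

# Mean accuracy sits near 0.5 because the latent evidence is zero-mean:
# individual questions are easier or harder (easiness spread), but the
# population as a whole is at chance.  Confidence varies cell by cell and
# tracks the evidence, which is what the downstream analyses exploit.
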