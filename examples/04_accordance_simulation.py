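"""Simulation 1: how similar are the judgments of confidence-selected panels?

Each iteration draws 10 questions, treats the first as the training
question, ranks all participants by their confidence on it, and builds
15-member panels three ways: the top 15 ranks ("highest"), evenly spread
over the top half ("higher"), and evenly spread over everyone ("mixed").
The accordance rate - the fraction of the 9 test questions on which two
members give the same answer - is averaged over all 105 member pairs.
"""

from crowdwise import GeneratorConfig, generate_dataset, run_accordance_simulation

dataset = generate_dataset(GeneratorConfig(seed=1))
results = run_accordance_simulation(dataset, n_iterations=1000, seed=1)

for r in results:
    print(f"{r.category:>7}: mean accordance {r.mean_rate:.3f} "
          f"[{r.ci_low:.3f}, {r.ci_high:.3f}]  ({r.n_iterations} iterations)")

# Accordance above 0.5 means panel members agree more than coin flips
# would.  High-confidence panels tend to agree slightly more (less diverse
# judgments); mixed panels preserve more diversity, which is what lets
# majority voting cancel individual errors.
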