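"""Does confidence predict accuracy on the same question? On other questions?

For every question we fit a logistic regression of correctness on
confidence (within-question), and for every ordered question pair a fit of
correctness on question j from confidence on question i (between-question).
If confidence carries real knowledge, within-question slopes should be
systematically larger.
"""

from crowdwise import (
    GeneratorConfig,
    apply_exclusions,
    between_question_analysis,
    generate_dataset,
    summarize_coefficients,
    within_question_analysis,
)

dataset = generate_dataset(GeneratorConfig(n_questions=15, seed=3))

within = summarize_coefficients(apply_exclusions(within_question_analysis(dataset)))
between = summarize_coefficients(apply_exclusions(between_question_analysis(dataset)))

print(f"within-question : {within.n_estimates} fits, "
      f"mean slope {within.mean_beta:.4f}, "
      f"{within.prop_ci_excluding_zero:.0%} of 95% CIs exclude 0")
print(f"between-question: {between.n_estimates} fits, "
      f"mean slope {between.mean_beta:.4f}, "
      f"{between.prop_ci_excluding_zero:.0%} of 95% CIs exclude 0")

# The within-question slope is clearly positive (confident answers are more
# often correct), while the between-question slope hovers near zero:
# confidence on one question says little about accuracy on another.
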