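"""The three vote-aggregation rules on one five-member example.

Five members answer a binary question (alternatives A and B): three choose
A with confidences 20, 30, 40 and two choose B with confidences 80, 90.
The rules can disagree about the group's answer.
"""

import numpy as np

from crowdwise import majority_vote, transmission_chain, weighted_confidence_vote

choices = list("AAABB")
confidences = [20, 30, 40, 80, 90]

print("majority rule        :", majority_vote(choices))
winner, winning_sum = weighted_confidence_vote(choices, confidences)
print(f"weighted confidence  : {winner} (winning sum {winning_sum:.0f} vs "
      f"{sum(confidences) - winning_sum:.0f})")
print("transmission chain   :",
      transmission_chain(list("ABA"), [np.nan, 80, 30], threshold=50))

# Majority picks A (3 votes to 2).  The weighted rule picks B because the
# two B voters are much more confident (170 vs 90).  The chain adopts the
# first member's A, lets the confident second member (80 >= 50) overwrite
# it with B, and ignores the third (30 < 50) - final answer B.
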