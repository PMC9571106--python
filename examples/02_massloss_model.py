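"""Factorial modelling of remaining litter mass with stepwise AIC selection.

Fits remaining-mass % on species, litter origin, precipitation treatment,
forest and time, selects the most parsimonious model by bidirectional AIC
search, and prints the sequential (Type-I) ANOVA table with the share of
total sums of squares per term.
"""

from litterlab import generate_litterbags
from litterlab.massloss import (records_to_model_frame, sequential_anova,
                                stepwise_select, term_label)

records = generate_litterbags(seed=42)
data = records_to_model_frame(records)

fit = stepwise_select(data)
print("selected terms:", ", ".join(term_label(t) for t in fit.terms))
print(f"AIC {fit.aic:.2f}, R^2 {fit.r2:.3f}\n")

table = sequential_anova(data, terms=list(fit.terms))
print(table.round(3).to_string(index=False))
print("\nTime dominates the variance budget; litter origin (litter_type) "
      "explains essentially nothing, matching a design in which drought "
      "acts on the decomposition site, not on litter quality.")
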