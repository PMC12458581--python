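"""Summed z-score signature activity on a disease cohort.

Each gene is z-scored across samples; a sample's score adds up-gene
z-scores and subtracts down-gene z-scores.  Scores are then associated
with ordinal disease severity and correlated between signatures.
"""

from liveraging import (
    GeneSignature, score_correlation, severity_association, signature_score,
    simulate_cohort, zscore_matrix,
)

aging = GeneSignature("aging",
                      up={f"u{i}" for i in range(50)},
                      down={f"d{i}" for i in range(50)})
cohort, states = simulate_cohort(aging, n_samples=200,
                                 severity_levels=["normal", "NAFLD", "NASH", "HCC"],
                                 effect=0.8, seed=4)
z = zscore_matrix(cohort.values)
aging_scores = signature_score(z, aging)

assoc = severity_association(aging_scores, states, ["normal", "NAFLD", "NASH", "HCC"])
print(f"aging-signature activity vs severity: r={assoc.r:.3f} "
      f"(p={assoc.p_value:.2e}, n={assoc.n})")

# an exposure that blocks the aging trajectory looks like the flipped signature
attenuating = aging.flipped()
attenuating.name = "attenuating-exposure"
expo_scores = signature_score(z, attenuating)
corr = score_correlation(aging_scores, expo_scores)
print(f"aging vs attenuating-exposure score correlation: r={corr.r:.2f}")
# r near -1 is the hallmark of an exposure signature that inverts the
# normal age-dependent expression program in patient samples too.
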