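"""Cohort simulation and context-induced-feeding statistics.

Simulates the default three-group cohort (fed, ghrelin-treated, fasted
training; 10/10/9 mice), computes each animal's context discrimination
(test intake in trained context A minus untrained context B), runs the
per-group sign-flip permutation contrast with Holm adjustment, and fits the
training-intake vs discrimination regression.
"""
import photocif as pc

design = pc.CohortDesign(seed=0)
cohort = pc.simulate_cohort(design, with_sessions=False)

disc = pc.context_discrimination(cohort.records)
contrasts = pc.group_contrasts(disc, seed=0)
print(contrasts.round(4).to_string(index=False))
# Only the fasted-trained group carries a programmed discrimination effect
# (0.3 g); its sign-flip p is exact (all 2^9 sign patterns enumerated).

train = cohort.records[cohort.records["phase"] == "training"]
train_mean = train.groupby("mouse")["intake_g"].mean()
for group, sub in disc.groupby("group"):
    x = train_mean.loc[sub["mouse"]].to_numpy()
    slope, intercept, r2 = pc.training_test_relation(x, sub["diff_g"].to_numpy())
    print(f"{group:>8}: discrimination = {slope:+.2f} x training + {intercept:+.2f}, "
          f"R^2 = {r2:.3f}")
# The fasted group is simulated with a per-mouse trait coupling training
# intake to discrimination, so its R^2 is substantially above the others'.
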