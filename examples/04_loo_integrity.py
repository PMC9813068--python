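"""Leave-one-out harness integrity: the memorizing-classifier canary.

A classifier that memorizes its training cases is perfect on anything it
has seen. Under a correct leave-one-out protocol it therefore collapses
to chance (every prediction 0.5): any deviation would prove the held-out
case leaked into its own training fold.
"""

from depthfuse import (
    MemorizingClassifier,
    StoredProbabilityClassifier,
    generate_cohort,
    leave_one_out,
    paper_preset,
)

cohort = generate_cohort(paper_preset("training_like", seed=7))[:100]

canary = leave_one_out(cohort, MemorizingClassifier(), seed=0)
print(f"memorizing classifier, {canary.n} folds:")
print(f"  unique predictions: {sorted(set(canary.predictions))}")
print(f"  accuracy: {canary.metrics.accuracy:.3f} (chance on this cohort)")

real = leave_one_out(cohort, StoredProbabilityClassifier(), seed=0)
print(f"\nstored-probability classifier, {real.n} folds:")
print(f"  accuracy: {real.metrics.accuracy:.3f}, F1: {real.metrics.f1:.3f}")

print(
    "\nThe canary's flat 0.5 output shows each case is excluded from its\n"
    "own training fold; the calibrated classifier then measures genuine\n"
    "out-of-sample performance."
)
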