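"""One adaptive classification session at a single EMA prompt.

Items are chosen by maximum expected information and the session stops as
soon as the 95% confidence interval around the interim estimate excludes
the classification cutoff (or at 5 items).
"""

from jitaema import (
    SelectorSpec,
    StoppingSpec,
    generate_synthetic_bank,
    run_session,
    start_session,
)

bank = generate_synthetic_bank(seed=1)

# scripted answers: a moderately fatigued respondent
answers = {item.item_id: 4 for item in bank}

session = start_session(
    bank,
    selector=SelectorSpec(kind="mei", rng_seed=0),
    stopping=StoppingSpec(kind="classification_confidence", max_items=5, confidence=0.95),
    cutoff=1.0,          # classify against z = 1 ("elevated" state)
    init_theta=0.5,      # prior knowledge, e.g. the previous prompt's estimate
)
result = run_session(session, answers)

print("items administered:", " -> ".join(result.items))
print(f"final estimate: theta={result.estimate.theta:.3f} (SE={result.estimate.se:.3f})")
print(f"stop reason: {result.stop_reason}")
c = result.classification
print(f"decision: {c.decision} the cutoff, confident={c.confident}, CI=({c.ci_lo:.2f}, {c.ci_hi:.2f})")
print("\nOnly as many questions are asked as the classification needs:")
print("states far from the cutoff usually stop after a single item.")
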