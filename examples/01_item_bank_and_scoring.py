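"""Item banks and latent-state scoring.

Builds a synthetic 13-item graded-response bank on the z-standardized
fatigue metric, then scores a short response pattern by MAP estimation.
"""

from jitaema import category_probabilities, estimate_map, generate_synthetic_bank, item_information

bank = generate_synthetic_bank(seed=1)
print(f"bank: {len(bank)} items, {bank.items[0].n_categories} categories each")

item = bank.items[0]
print(f"\n{item.item_id}: a={item.discrimination:.2f}, thresholds={[round(b, 2) for b in item.thresholds]}")
for theta in (-1.0, 0.0, 1.0, 2.0):
    probs = category_probabilities(item, theta)
    info = item_information(item, theta)
    print(f"  theta={theta:+.1f}: P(categories)={[round(float(p), 2) for p in probs]}, information={info:.2f}")

# a person endorsing moderately high categories on three items
responses = [(bank.items[0], 4), (bank.items[5], 3), (bank.items[9], 4)]
est = estimate_map(responses)
print(f"\nMAP after 3 responses: theta={est.theta:.3f}, SE={est.se:.3f}")
print("theta is the momentary latent state in z units; the SE is its")
print("standard error of measurement (prior SD 1.0 with no responses).")
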