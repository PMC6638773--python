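"""Turn a classified stream into a daily signal and correlate it with a
reference health indicator.

Generates a 77-day paired stream (relevant-post counts share correlation
0.4 with the health series by construction), smooths both series with a
7-day trailing moving average, and compares the relevance-filtered signal
with the raw unfiltered volume.
"""

from symptweet import (
    PairedStreamSpec,
    correlate,
    daily_signal,
    generate_paired_stream,
    moving_average,
)

tweets, health, truth = generate_paired_stream(PairedStreamSpec(n_days=77, rho=0.4, seed=1))
stamps = [t.timestamp for t in tweets]
labels = [t.label for t in tweets]

filtered = moving_average(daily_signal(stamps, labels, mode="count"), 7)
unfiltered = moving_average(daily_signal(stamps, ["relevant"] * len(stamps), mode="count"), 7)
smoothed_health = moving_average(health, 7)

res_f = correlate(filtered, smoothed_health)
res_u = correlate(unfiltered, smoothed_health)

print(f"stream: {len(tweets)} posts over {len(health)} days")
print(f"relevance-filtered signal vs health: r = {res_f.r:.3f} (p = {res_f.p:.2g}, n = {res_f.n})")
print(f"unfiltered volume      vs health: r = {res_u.r:.3f} (p = {res_u.p:.2g}, n = {res_u.n})")
print()
print("-> the irrelevant chatter fluctuates independently of the health")
print("   indicator, so filtering it out recovers the planted correlation")
print("   while the raw volume signal is dominated by noise.")
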