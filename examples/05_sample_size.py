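"""Log-rank sample-size planning with the Schoenfeld formula.

How many deaths must a cohort accumulate to detect, with two-sided alpha
0.05 and 80% power, a hazard ratio of 2 for an exposure present in 15% of
patients — and how many patients does that take if about one third die
during follow-up?
"""

from dgcfusion import required_events, required_sample

events = required_events(alpha=0.05, power=0.8, exposed_fraction=0.15, hazard_ratio=2.0)
cohort = required_sample(events, event_rate=1 / 3)

print(f"required events:  {events}")
print(f"required cohort:  {cohort}  (at an event rate of 1/3)")
for p in (0.05, 0.15, 0.30, 0.50):
    d = required_events(0.05, 0.8, p, 2.0)
    print(f"  exposed fraction {p:.2f} -> {d} events "
          "(fewest when exposure is balanced)")
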