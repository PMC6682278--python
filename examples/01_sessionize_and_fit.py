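"""Sessionize a raw click log and fit a first-order Markov chain.

Generates a small synthetic field-trial log, cuts it into sessions with
the 30-minute inactivity heuristic, and estimates the transition matrix
(with absorbing exit state), the initial distribution and the page-view
table.
"""

import pandas as pd

from clickchain import (
    GeneratorConfig,
    StateSpace,
    fit,
    generate_log,
    page_view_summary,
    sessionize,
)

config = GeneratorConfig(n_users=6, sessions_per_user_mean=40, sessions_per_user_sd=15, seed=3)
raw, truth = generate_log(config)
print(f"log: {len(raw.events)} events from {config.n_users} users")

sessions = sessionize(raw, gap_threshold=pd.Timedelta(minutes=30))
lengths = [len(s) for s in sessions]
print(
    f"sessionized into {len(sessions)} sessions "
    f"(true count {len(truth.sessions)}), mean trail length "
    f"{sum(lengths) / len(lengths):.2f} actions"
)

states = StateSpace(pages=tuple(dict.fromkeys(p for s in sessions for p in s.trail)))
model = fit(sessions, states)

print("\nTransition matrix P (rows: source page, columns: destination, exit last):")
print(model.to_frame().round(2).to_string())
print("\nInitial distribution (share of sessions starting on each page):")
for label, p in zip(states.labels, model.pi):
    if p > 0:
        print(f"  {label:12s} {p:.3f}")
print("\nPage views (absolute and % of all views):")
print(page_view_summary(sessions).to_string())
print(
    "\nEach P row sums to 1: the entries are the probabilities of the next"
    "\nclick from that page, with 'Exit' the probability of leaving the app."
)
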