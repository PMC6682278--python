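# Methods

This note documents the models and procedures implemented in
`clickchain`, the parameters that matter, the numerical and design
choices made where the design was open, and what the synthetic data can
and cannot show.

## Sessionization

Mobile-app logs often carry no session identifier, so sessions are
reconstructed from timestamps: within one user, a gap of inactivity
strictly greater than `gap_threshold` (default 30 minutes) opens a new
session. The boundary is inclusive — a gap of exactly 30 minutes stays
in-session, reading "no more than 30 minutes of inactivity" literally.
Timestamps are normalized to UTC on ingest (naive stamps assumed UTC) so
gaps are timezone-stable. Consecutive identical pages within a session
are collapsed to one state occurrence by default, because page refreshes
are not navigation and the fitted chain is expected to have an empty
diagonal; the flag `collapse_repeats=False` keeps them for logs where
refreshes matter. Session length for filtering (default 2–20 actions,
used by the heatmap export) is counted on the collapsed trail, exit
excluded. Raw event counts are preserved per session (`n_events`) so
event conservation holds whatever the collapsing flag.

## The chain

States are the app's pages plus a surrogate exit state, always ordered
pages-first, exit last, for reproducible serialization. Counting adds
one transition per adjacent trail pair plus one final-page → exit per
session; a one-page session contributes exactly one exit transition.
Normalization divides each row by its sum; rows with no observed
departures (always including exit) are left all-zero and reported as
*dangling* rather than invented. No smoothing is applied at the global
estimation stage — zeros mean "not observed". π is the empirical
distribution of first pages with zero exit mass.

Likelihood is computed in log space (natural log) so long trails cannot
underflow; a zero-probability step yields −∞ rather than an error, which
keeps argmax comparisons meaningful. The initial term log π is excluded
by default — the clustering likelihood is defined as the product of
transition probabilities only — and can be included with a flag.

Simulation draws the first state from π (exit excluded) and then walks
rows of P until exit is drawn or `max_len` (default 100) states have
been emitted, in which case the trail is flagged truncated. Rows are
renormalized by their sum at sampling time: this is deliberate, because
the packaged reference matrix stores published values at their printed
two-decimal precision, whose rows sum to 0.99–1.01. Reaching a state
with no outgoing mass raises an error naming the state.

In the packaged reference model, probabilities printed as absent ("—")
and those printed "0.00" are both stored as exactly 0 — treated as
unobserved, not structurally impossible. The reference π places 0.769
on Coach (the published share of sessions starting there); the
remaining 0.231 is split Track 0.15 / Competition 0.081. Only the total
non-Coach mass is published; the split is an emulation choice guided by
the observation that interrupted sessions most often resumed on the
Track and Competition pages.

## Hard-EM sequence clustering

The implementation follows the classification-EM scheme exactly:
uniform-random initial assignment, per-cluster chain construction,
argmax reassignment by product-of-transitions likelihood, convergence
when the assignment vector repeats, with a `max_iter` cap (default 100;
`converged=False` on expiry). Three points the scheme leaves open were
resolved as follows:

* **Smoothing.** The product likelihood is zero whenever a trail uses a
  transition unseen in a cluster, which makes reassignment degenerate on
  sparse clusters. A pseudocount (default 0.5, configurable) is added to
  every cell of every non-exit row (exit column included) before
  normalizing cluster chains. As the pseudocount → 0 on data where every
  transition is observed in every cluster, the cluster chains converge
  to the unsmoothed per-cluster MLE.
* **Ties.** Argmax ties break to the lowest cluster index, making runs
  deterministic given the seed.
* **Empty clusters.** A cluster left empty is re-seeded with the single
  worst-fitting trail (lowest log-likelihood under its current cluster),
  keeping K constant.

Hard EM is a local search: because each cluster chain is normalized
row-wise, a merged cluster scores trails with disjoint page support as
well as separate pure clusters do, so single runs can collapse
components. The optional multi-restart helper (`n_restarts`) runs
independent seeds (spawned from one root seed) and keeps the run with
the highest total assigned log-likelihood, which reliably selects the
separated solution; 10 restarts are used in the recovery tests. The
total assigned log-likelihood after each reassignment is recorded
(`trace`) and is non-decreasing on the test fixtures; the empty-cluster
rescue can in principle break monotonicity, which is why the trace is
kept available for inspection.

`classify` scores an unseen trail under every cluster chain and returns
the argmax plus the full log-likelihood vector. No automatic choice of
K is provided.

## Synthetic field-trial generator

The generator emulates the trial's observable structure, with defaults
fixed to its reported descriptives: 22 users; per-user session counts
negative-binomial with mean 37 and SD 29.35 (r = μ²/(σ²−μ), minimum 1;
SD 0 selects a fixed count, used for large calibration runs); sessions
drawn from three archetype chains mixed 0.45 route-tracking / 0.35
gamification / 0.20 bug-report (the mixture is not published; these
weights reflect the described prominence of route tracking). Trail
lengths arise from the chains rather than being imposed and average
about five actions. Intra-session gaps are uniform on 5–120 s and
inter-session gaps uniform on 45 min–16 h, keeping both strictly on
their side of the 30-minute threshold so the true session partition is
recoverable exactly; with ~37 sessions per user this spreads a user's
activity across roughly three weeks, mirroring the 25-day trial window.
Users start staggered across the first day. There is no diurnal or
day-of-week structure, no dropout over time, no push-notification
response, and gaps never straddle the threshold — so passing
sessionization tests show correctness of the gap rule, not robustness
to ambiguous real-world gaps near 30 minutes.

The three archetype chains are design objects, not estimates. Their
values were chosen for separability: the clustering likelihood ignores
π, so archetypes must differ in their transitions, and the Coach row —
almost every session's first step — keeps only 0.05 exit mass and sends
nearly all probability toward the archetype's distinctive pages
(Competition/Team, Track, or Personal). Later pages carry 0.25–0.6 exit
mass, giving mean length ≈ 5. Any two archetypes differ by L1 distance
≥ 1 on at least three rows. Residual classification error (~4–5%) comes
from genuinely ambiguous short trails such as a bare `[Coach]`.

## Graph export

Edge filtering keeps every transition with probability ≥ cutoff
(default 0.13, the published display threshold). The published figure
additionally displayed the strongest incoming edge of the Trophies and
Personal pages, which would otherwise be visually isolated; this is
generalized to *any* non-exit page whose incoming edges all fall below
the cutoff, which reproduces the published behaviour on the reference
matrix (only Trophies needs the rescue there — the strongest incoming
edge of Personal, Bug report → Personal at 0.29, already clears the
cutoff). Ties on the maximum break by source order. Exported node-link
JSON serializes probabilities at full precision so re-import is
bit-exact; the exit node is included with a flag so renderers may hide
it.

## Problem sizes and tolerances

The calibration round trip simulates 50,000 sessions (≈ 257,000 events)
from the reference chain, which bounds the sampling error of each fitted
entry well below the ±0.01 used when comparing to the published values;
the clustering recovery fixtures use 100 sessions per archetype. Row
sums of fitted matrices are checked to 1e-9. The packaged reference
matrix is stored at its printed two-decimal precision, so its row sums
are checked within the accumulated half-ULP of printing (±0.005 per
printed entry) rather than a fixed ±0.005 per row, which the printed
data itself would violate.
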