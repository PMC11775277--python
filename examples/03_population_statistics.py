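"""Population statistics on a simulated assay: cumulative behavioral
probabilities after stimulus onset, the post-onset transition matrix, and
a chi-square comparison of Hunch counts before vs during stimulation.

Cumulative probability = fraction of larvae tracked at stimulus onset
that perform the action at least once in the window.  Transition rows are
normalized over observed transitions; cells under 3 % are hidden for
display but kept in the data.
"""

from ethome import stats
from ethome.pipeline import coarse_from_truth, compute_series
from ethome.synth import PopulationConfig, default_protocol, simulate_population, truth_to_frame

protocol = default_protocol()  # 4 m/s air puff, 60–90 s
cfg = PopulationConfig(n_larvae=60, dropout=0.15, seed=3)
trackset, truth = simulate_population(cfg, protocol)
truth_df = truth_to_frame(truth)
intervals = coarse_from_truth(truth_df)
for iv, row in zip(intervals, truth_df.itertuples(index=False)):
    iv.refined_label = "Crawl" if row.label == "FastCrawl" else row.label

onset = protocol.onset
print("cumulative probabilities in the first 5 s after onset "
      "(denominator: larvae tracked at onset):")
for action in ("Hunch", "HeadAndTail", "CShape", "StaticBend", "Roll"):
    p, n = stats.cumulative_probability(intervals, trackset, action, (onset, onset + 5.0))
    print(f"  {action:12s} p={p:.3f}  (n={n})")

tm = stats.transition_matrix(intervals, window=(onset, onset + 3.0))
print("\ntransition probabilities (first 3 s, >=3% shown):")
print(tm.displayed().round(2).fillna("").to_string())

p_stim, n_stim = stats.cumulative_probability(intervals, trackset, "Hunch", (onset, onset + 5.0))
p_base, n_base = stats.cumulative_probability(intervals, trackset, "Hunch", (onset - 5.0, onset))
table = [
    [round(p_stim * n_stim), n_stim - round(p_stim * n_stim)],
    [round(p_base * n_base), n_base - round(p_base * n_base)],
]
chi2, df, p = stats.chi2_compare(table)
print(f"\nHunch during vs before stimulation: chi2={chi2:.2f}, df={df}, p={p:.2e}")
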