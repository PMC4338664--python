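"""Unsupervised specialization on moving-bar orientations (scaled demo).

Eight predictors compete for three orientations over two presentations
each; after learning, a frozen test presentation shows which network each
orientation recruited.  Runs in well under a minute.
"""

from evsn import ArchitectureConfig, recruitment_report, run_orientation_experiment

config = ArchitectureConfig(n_esns=8)
report, learner = run_orientation_experiment(
    config, seed=1, repetitions=2, test_repetitions=1,
    presentation_s=1.0, pause_s=0.5, orientations=(0, 60, 120),
)

modal = report.interval_modal_winners()
print("orientation -> modal winning ESN (frozen test phase):")
for row in modal[~modal.learn].itertuples():
    print(f"  {row.label:>7}: ESN {row.winner}")

n_recruited, _ = recruitment_report(report)
print(f"training samples per ESN: {report.counts.tolist()}")
print(f"recruited (count > 1% of gated training ticks): {n_recruited}")
# Distinct orientations recruit distinct predictors; unused networks stay
# available for future features.  The full-scale experiments (9
# orientations, pools of 8 or 20) are run by tests/test_acceptance.py and
# scripts/acceptance.py.
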