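"""Inject a known heterochrony into synthetic schedules and recover it.

Four species share one uniform onset schedule (synchronic development);
species 2 is delayed by 20 percent points on two characters whose onsets
sit just below the 50% landmark, so both flips are visible exactly
there. Recall/precision score the strict set-based detector against the
injected truth.
"""

from ontochron import (
    OnsetShift,
    SimulationConfig,
    TimeFrame,
    recovery_experiment,
)

onsets = tuple((i + 1) * 100.0 / 11 for i in range(10))  # 9.1%, 18.2%, ...
shift = OnsetShift("Species_2", characters={4, 5}, shift=20.0)
cfg = SimulationConfig(
    n_species=4, n_characters=10, onset_percents=onsets,
    heterochronies=(shift,), missing_rate=0.0, seed=42,
)

result = recovery_experiment(cfg, TimeFrame((25, 50, 75)))
print(f"injected: {shift.species} late on characters {sorted(shift.characters)}")
print(f"precision={result.precision:.2f}  recall={result.recall:.2f}")
print(f"(the pipeline reported {result.n_reported} strict event(s) "
      f"for {result.n_injected} injected shift(s))\n")
for e in result.report.events:
    print(f"[{e.mode}] {e.species} {e.direction} at {e.landmark:g}%: "
          f"{sorted(e.characters)}")
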